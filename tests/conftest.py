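import textwrap

import pytest

from kinnet import (
    Metabolite,
    Model,
    Reaction,
    builtin_rate_law,
)

MINIMAL_SBML = textwrap.dedent("""\
    <?xml version="1.0" encoding="UTF-8"?>
    <sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
      <model id="minimal" name="minimal">
        <listOfCompartments>
          <compartment id="cell" size="1" constant="true" spatialDimensions="3"/>
        </listOfCompartments>
        <listOfSpecies>
          <species id="A" compartment="cell" initialConcentration="1"
                   boundaryCondition="false" constant="false" hasOnlySubstanceUnits="false"/>
          <species id="B" compartment="cell" initialConcentration="0"
                   boundaryCondition="true" constant="false" hasOnlySubstanceUnits="false"/>
        </listOfSpecies>
        <listOfReactions>
          <reaction id="r1" reversible="false" fast="false">
            <listOfReactants>
              <speciesReference species="A" stoichiometry="1" constant="true"/>
            </listOfReactants>
            <listOfProducts>
              <speciesReference species="B" stoichiometry="1" constant="true"/>
            </listOfProducts>
            <kineticLaw>
              <math xmlns="http://www.w3.org/1998/Math/MathML">
                <apply><times/><ci>k</ci><ci>A</ci></apply>
              </math>
              <listOfLocalParameters>
                <localParameter id="k" value="0.25"/>
              </listOfLocalParameters>
            </kineticLaw>
          </reaction>
        </listOfReactions>
      </model>
    </sbml>
""")

SBML_WITH_EVENT = MINIMAL_SBML.replace(
    "</listOfReactions>",
    """</listOfReactions>
        <listOfEvents>
          <event id="e1" useValuesFromTriggerTime="true">
            <trigger initialValue="true" persistent="true">
              <math xmlns="http://www.w3.org/1998/Math/MathML"><true/></math>
            </trigger>
          </event>
        </listOfEvents>""",
)

# a small pathway: 4 compounds (two aliasing the same accession), two
# catalyzing genes, a map entry, 3 reactions (one reversible, one a
# substrate/product duplicate of another)
SAMPLE_KGML = textwrap.dedent("""\
    <?xml version="1.0"?>
    <pathway name="path:syn00001" org="syn" number="00001" title="synthetic pathway">
      <entry id="1" name="cpd:C00001" type="compound">
        <graphics name="Alpha" x="100" y="100" type="circle"/>
      </entry>
      <entry id="2" name="cpd:C00002" type="compound">
        <graphics name="Beta" x="200" y="100" type="circle"/>
      </entry>
      <entry id="3" name="cpd:C00003" type="compound">
        <graphics name="Gamma" x="300" y="100" type="circle"/>
      </entry>
      <entry id="4" name="cpd:C00002" type="compound">
        <graphics name="Beta-alias" x="200" y="200" type="circle"/>
      </entry>
      <entry id="5" name="gene:G1" type="gene" reaction="rn:R0001">
        <graphics name="enzyme one" x="150" y="50" type="rectangle"/>
      </entry>
      <entry id="6" name="gene:G2" type="gene" reaction="rn:R0002">
        <graphics name="enzyme two" x="250" y="50" type="rectangle"/>
      </entry>
      <entry id="7" name="path:syn00002" type="map">
        <graphics name="another map" x="400" y="400" type="roundrectangle"/>
      </entry>
      <reaction id="10" name="rn:R0001" type="irreversible">
        <substrate id="1" name="cpd:C00001"/>
        <product id="2" name="cpd:C00002"/>
      </reaction>
      <reaction id="11" name="rn:R0002" type="reversible">
        <substrate id="2" name="cpd:C00002"/>
        <product id="3" name="cpd:C00003"/>
      </reaction>
      <reaction id="12" name="rn:R0003" type="irreversible">
        <substrate id="1" name="cpd:C00001"/>
        <product id="4" name="cpd:C00002"/>
      </reaction>
      <relation entry1="5" entry2="6" type="ECrel">
        <subtype name="compound" value="2"/>
      </relation>
    </pathway>
""")

KGML_DANGLING = SAMPLE_KGML.replace(
    '<substrate id="1" name="cpd:C00001"/>',
    '<substrate id="99" name="cpd:C09999"/>',
    1,
)


@pytest.fixture
def minimal_sbml(tmp_path):
    p = tmp_path / "minimal.xml"
    p.write_text(MINIMAL_SBML)
    return p


@pytest.fixture
def sbml_with_event(tmp_path):
    p = tmp_path / "event.xml"
    p.write_text(SBML_WITH_EVENT)
    return p


@pytest.fixture
def sample_kgml(tmp_path):
    p = tmp_path / "sample.kgml"
    p.write_text(SAMPLE_KGML)
    return p


@pytest.fixture
def kgml_dangling(tmp_path):
    p = tmp_path / "dangling.kgml"
    p.write_text(KGML_DANGLING)
    return p


def decay_model(k: float = 0.1, a0: float = 1.0, b0: float = 0.0) -> Model:
    """A -> B irreversible mass action."""
    m = Model(id="decay")
    m.add_metabolite(Metabolite(id="A", initial_concentration=a0))
    m.add_metabolite(Metabolite(id="B", initial_concentration=b0))
    m.add_reaction(
        Reaction(
            id="r1",
            reactants={"A": 1},
            products={"B": 1},
            rate_law=builtin_rate_law("Irreversible mass action"),
            parameter_values={"k": k},
        )
    )
    m.validate()
    return m


def influx_decay_model(v: float = 2.0, k: float = 0.5) -> Model:
    """Constant influx to A, first-order decay of A."""
    from kinnet import custom_rate_law

    m = Model(id="influx_decay")
    m.add_metabolite(Metabolite(id="A", initial_concentration=0.0))
    m.add_reaction(
        Reaction(
            id="influx",
            reactants={},
            products={"A": 1},
            rate_law=custom_rate_law("constant influx", "v", ["v"]),
            parameter_values={"v": v},
        )
    )
    m.add_reaction(
        Reaction(
            id="decay",
            reactants={"A": 1},
            products={},
            rate_law=builtin_rate_law("Irreversible mass action"),
            parameter_values={"k": k},
        )
    )
    m.validate()
    return m


def equilibrium_model(kf: float = 2.0, kr: float = 1.0, total: float = 3.0) -> Model:
    """A <-> B reversible mass action starting all-A."""
    m = Model(id="equilibrium")
    m.add_metabolite(Metabolite(id="A", initial_concentration=total))
    m.add_metabolite(Metabolite(id="B", initial_concentration=0.0))
    m.add_reaction(
        Reaction(
            id="r1",
            reactants={"A": 1},
            products={"B": 1},
            reversible=True,
            rate_law=builtin_rate_law("Reversible mass action"),
            parameter_values={"kf": kf, "kr": kr},
        )
    )
    m.validate()
    return m


@pytest.fixture
def decay():
    return decay_model()


@pytest.fixture
def equilibrium():
    return equilibrium_model()
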