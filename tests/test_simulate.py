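import math

import numpy as np
import pytest
from scipy.linalg import null_space

from kinnet import (
    ScanItem,
    find_steady_state,
    generate_synthetic_model,
    parameter_scan,
    simulate_time_course,
)
from kinnet.errors import ConfigurationError, LookupErrorKN
from kinnet.model import Metabolite, Model, Reaction
from kinnet.ratelaws import builtin_rate_law, custom_rate_law

from ._oracle import rk4_time_course
from .conftest import decay_model, equilibrium_model, influx_decay_model


class TestTimeCourse:
    def test_exponential_decay_closed_form(self):
        traj = simulate_time_course(decay_model(k=0.1), duration=10.0, n_points=100)
        assert traj.column("A")[-1] == pytest.approx(math.exp(-1.0), rel=1e-5)
        assert traj.column("B")[-1] == pytest.approx(1.0 - math.exp(-1.0), rel=1e-5)

    def test_sampling_grid(self):
        traj = simulate_time_course(decay_model(), duration=10.0, n_points=50)
        assert len(traj.times) == 51
        assert traj.times[0] == 0.0
        assert traj.times[-1] == 10.0
        assert np.all(np.diff(traj.times) > 0)

    def test_row0_is_initial_state(self):
        m = decay_model(a0=2.0, b0=0.5)
        traj = simulate_time_course(m, 1.0, 10)
        assert traj.concentrations[0].tolist() == [2.0, 0.5]

    def test_mass_conservation_pointwise(self):
        traj = simulate_time_course(decay_model(), 10.0, 100, abs_tol=1e-12)
        total = traj.column("A") + traj.column("B")
        assert np.allclose(total, 1.0, atol=1e-8)

    def test_fixed_metabolite_constant(self):
        m = decay_model()
        m.metabolite("A").fixed = True
        traj = simulate_time_course(m, 10.0, 20)
        assert np.all(traj.column("A") == 1.0)
        assert traj.column("B")[-1] > 0.5  # constant influx from clamped A

    def test_unparameterized_reaction_is_configuration_error(self):
        m = decay_model()
        m.reaction("r1").rate_law = None
        m.reaction("r1").parameter_values = {}
        with pytest.raises(ConfigurationError):
            simulate_time_course(m, 1.0, 10)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_time_course(decay_model(), 0.0, 10)

    def test_tsv_export(self, tmp_path):
        traj = simulate_time_course(decay_model(), 1.0, 5)
        path = tmp_path / "traj.tsv"
        traj.to_tsv(path)
        header = path.read_text().splitlines()[0].split("\t")
        assert header == ["time", "A", "B"]


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_matches_fixed_step_rk4_on_random_networks(self, seed):
        """Adaptive stiff solver vs an independent RK4 at step 1e-3*T."""
        rng = np.random.default_rng(seed)
        n_species = int(rng.integers(3, 9))
        model = generate_synthetic_model(
            n_species,
            n_species + 2,
            law_mix={"mass_action_irreversible": 0.6, "mass_action_reversible": 0.4},
            seed=seed,
        )
        duration = 20.0
        traj = simulate_time_course(model, duration, n_points=100, abs_tol=1e-12)
        oracle = rk4_time_course(model, duration, n_steps=1000)
        for sid, series in oracle.items():
            expected = series[::10]  # oracle sampled 10x denser
            ours = traj.column(sid)
            scale = np.maximum(np.abs(expected), 1e-6)
            rel_err = np.max(np.abs(ours - expected) / scale)
            assert rel_err < 1e-4, f"{sid}: rel err {rel_err}"

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_conservation_laws_preserved(self, seed):
        """Left-null-space vectors of N stay constant along trajectories
        of closed mass-action networks."""
        model = generate_synthetic_model(
            5, 6,
            law_mix={"mass_action_irreversible": 0.5, "mass_action_reversible": 0.5},
            seed=seed,
        )
        abs_tol = 1e-8
        traj = simulate_time_course(model, 50.0, 100, rel_tol=1e-10, abs_tol=abs_tol)
        ids = traj.metabolite_order
        N = np.zeros((len(ids), len(model.reactions)))
        for j, r in enumerate(model.reactions):
            for sid, coef in r.reactants.items():
                N[ids.index(sid), j] -= coef
            for sid, coef in r.products.items():
                N[ids.index(sid), j] += coef
        left_null = null_space(N.T)
        assert left_null.shape[1] >= 1  # closed network conserves total mass
        conserved = traj.concentrations @ left_null
        drift = np.max(np.abs(conserved - conserved[0]), axis=0)
        assert np.all(drift < 10 * abs_tol)


class TestSteadyState:
    def test_influx_decay_closed_form(self):
        ss = find_steady_state(influx_decay_model(v=2.0, k=0.5))
        assert ss.status == "found"
        assert ss.concentrations["A"] == pytest.approx(4.0, rel=1e-6)
        assert ss.fluxes["influx"] == pytest.approx(2.0)
        assert ss.fluxes["decay"] == pytest.approx(2.0, rel=1e-6)

    def test_equilibrium_partition(self):
        ss = find_steady_state(equilibrium_model(kf=2.0, kr=1.0, total=3.0))
        assert ss.status == "found"
        assert ss.concentrations["A"] == pytest.approx(1.0, rel=1e-6)
        assert ss.concentrations["B"] == pytest.approx(2.0, rel=1e-6)

    def test_divergent_system_not_found(self):
        m = Model(id="divergent")
        m.add_metabolite(Metabolite(id="A"))
        m.add_reaction(
            Reaction(
                id="influx", reactants={}, products={"A": 1},
                rate_law=custom_rate_law("constant", "v", ["v"]),
                parameter_values={"v": 1.0},
            )
        )
        ss = find_steady_state(m)
        assert ss.status == "not_found"

    def test_residual_within_tolerance(self):
        tol = 1e-9
        ss = find_steady_state(influx_decay_model(), tolerance=tol)
        assert ss.residual_norm <= tol

    def test_flat_trajectory_consistency(self):
        """Injecting steady-state concentrations as initial state yields a
        flat trajectory."""
        m = influx_decay_model(v=2.0, k=0.5)
        ss = find_steady_state(m)
        m.metabolite("A").initial_concentration = ss.concentrations["A"]
        traj = simulate_time_course(m, 100.0, 50)
        a = traj.column("A")
        assert np.max(np.abs(a - a[0])) < 1e-6

    def test_json_export(self, tmp_path):
        ss = find_steady_state(influx_decay_model())
        path = tmp_path / "ss.json"
        ss.to_json(path)
        import json

        doc = json.loads(path.read_text())
        assert doc["status"] == "found"
        assert doc["concentrations"]["A"] == pytest.approx(4.0, rel=1e-6)


class TestParameterScan:
    def test_null_perturbation_outputs_identical(self, decay):
        base, pert = parameter_scan(
            decay, [ScanItem("reaction.r1.k", 0.1, 0.1)], duration=10.0, n_points=20
        )
        assert np.array_equal(base.concentrations, pert.concentrations)

    def test_model_restored_byte_identical(self, decay):
        before = decay.to_json()
        parameter_scan(
            decay, [ScanItem("reaction.r1.k", 0.1, 0.9)], duration=5.0, n_points=10
        )
        assert decay.to_json() == before

    def test_multi_parameter_endpoints(self, decay):
        base, pert = parameter_scan(
            decay,
            [
                ScanItem("reaction.r1.k", 0.1, 0.5),
                ScanItem("metabolite.A.initial", 1.0, 2.0),
            ],
            duration=1.0,
            n_points=10,
        )
        assert pert.concentrations[0, 0] == 2.0  # perturbed initial state
        assert base.concentrations[0, 0] == 1.0
        assert pert.column("A")[-1] != base.column("A")[-1]

    def test_unresolvable_target(self, decay):
        with pytest.raises(LookupErrorKN):
            parameter_scan(decay, [ScanItem("global.nope", 0, 1)], duration=1.0)

    def test_steadystate_mode(self):
        m = influx_decay_model(v=2.0, k=0.5)
        base, pert = parameter_scan(
            m, [ScanItem("reaction.decay.k", 0.5, 1.0)], mode="steadystate"
        )
        assert base.concentrations["A"] == pytest.approx(4.0, rel=1e-6)
        assert pert.concentrations["A"] == pytest.approx(2.0, rel=1e-6)
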