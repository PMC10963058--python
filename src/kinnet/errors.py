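"""Exception hierarchy shared across the package."""


class KinnetError(Exception):
    """Base class for all package errors."""


class EquationParseError(KinnetError):
    """A reaction-equation string does not match the grammar."""


class IntegrityError(KinnetError):
    """A model edit or construction would break referential integrity."""


class ConflictError(KinnetError):
    """A new element id collides with an existing one."""


class EvaluationError(KinnetError):
    """A rate law could not be evaluated (unbound symbol, singularity)."""


class ConfigurationError(KinnetError):
    """A model is not ready for the requested task (e.g. missing rate laws)."""


class SolverError(KinnetError):
    """Numerical integration failed."""


class LookupErrorKN(KinnetError):
    """A referenced element, module, slot or target path does not exist."""


class ComparisonError(KinnetError):
    """Two states cannot be compared (empty intersection, no steady state)."""


class UnsupportedFeatureError(KinnetError):
    """An input file uses a construct outside the supported subset."""


class FetchError(KinnetError):
    """A remote resource is unavailable and not cached."""


class ValidationError(KinnetError):
    """An input value fails validation (EC number, units, arguments)."""
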