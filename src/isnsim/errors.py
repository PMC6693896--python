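"""Exception hierarchy shared across the package."""


class IsnsimError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(IsnsimError, ValueError):
    """A parameter value violates its documented domain."""


class SchemaError(IsnsimError, ValueError):
    """A config / network / validation document does not match its schema."""


class TopologyError(IsnsimError, ValueError):
    """A morphology or compartment graph is not a rooted tree."""


class NumericalInstabilityError(IsnsimError, RuntimeError):
    """The integrator produced non-finite state or an out-of-range gate."""


class CapabilityError(IsnsimError, ValueError):
    """A requested observable cannot be computed from the recorded outputs."""


class ProtocolError(IsnsimError, ValueError):
    """An experiment protocol is internally inconsistent or inapplicable."""


class FeatureExtractionError(IsnsimError, ValueError):
    """A voltage trace could not be reduced to features."""


class OptimizationError(IsnsimError, RuntimeError):
    """The model-fitting stage failed to produce any viable candidate."""
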