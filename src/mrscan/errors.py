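"""Exception hierarchy."""


class MrscanError(Exception):
    """Base class for all package errors."""


class ValidationError(MrscanError):
    """Input data violates a documented invariant (bad field value, duplicate rsid...)."""


class ConfigurationError(MrscanError):
    """A configuration file or column map is malformed or incomplete."""


class InsufficientInstrumentsError(MrscanError):
    """An estimator was asked to run with fewer instruments than it can identify."""
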