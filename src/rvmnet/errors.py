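"""Exception hierarchy shared by all pipeline stages."""


class RvmnetError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(RvmnetError):
    """A simulation or pipeline configuration violates its invariants."""


class InvalidInputError(RvmnetError):
    """An operation received data outside its contract (wrong range, mismatched lengths...)."""


class DegenerateInputError(RvmnetError):
    """Input is formally valid but makes the requested estimate undefined (e.g. zero dispersion)."""


class InsufficientDataError(RvmnetError):
    """Too few observations to fit the requested model."""


class ParseError(RvmnetError):
    """A file could not be parsed; the message names the offending line/row/column."""


class PipelineError(RvmnetError):
    """A pipeline stage failed; the message names the stage and the cause."""
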