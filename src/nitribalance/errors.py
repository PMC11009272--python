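class NitribalanceError(Exception):
    """Base class for all package errors."""


class ParameterError(NitribalanceError, ValueError):
    """An argument or configuration field is invalid; the message names it."""


class FormatError(NitribalanceError, ValueError):
    """An input file is structurally invalid; the message locates the defect."""


class PipelineError(NitribalanceError, RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""
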