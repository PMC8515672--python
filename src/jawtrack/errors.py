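"""Exception hierarchy."""


class JawtrackError(Exception):
    """Base class for all jawtrack errors."""


class InputError(JawtrackError):
    """Malformed or non-finite input data."""


class InsufficientCorrespondenceError(JawtrackError):
    """Fewer than three common marker labels between two point sets."""


class DegenerateGeometryError(JawtrackError):
    """Marker configuration too degenerate (collinear) for a unique rigid fit."""


class ParseError(InputError):
    """A file did not match its documented schema."""


class PipelineError(JawtrackError):
    """A pipeline stage failed; the stage name is in the message."""
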