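"""Exception hierarchy.

Every error raised deliberately by the package derives from
:class:`EmotopicError`, so callers (and the CLI) can distinguish pipeline
failures from programming errors.
"""


class EmotopicError(Exception):
    """Base class for all package errors."""


class FormatError(EmotopicError):
    """A file does not conform to its declared format."""


class ReferentialIntegrityError(EmotopicError):
    """A tweet references a user absent from the user table."""


class ParameterError(EmotopicError):
    """An argument is outside its documented domain."""


class RangeError(EmotopicError):
    """A parsed value lies outside its documented range."""


class DegenerateSampleError(EmotopicError):
    """A statistical routine received a sample it cannot handle."""


class PipelineError(EmotopicError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code
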