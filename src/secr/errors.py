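"""Exception hierarchy shared across the package."""


class SecrError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SecrError, ValueError):
    """A caller-supplied value violates an operation's preconditions."""


class SchemaError(SecrError, ValueError):
    """A configuration or data file does not match its documented schema."""


class DicomFormatError(SecrError):
    """A DICOM object is missing attributes required for interpretation."""


class DicomModalityError(DicomFormatError, TypeError):
    """A DICOM file of the wrong modality was passed to a reader."""


class GeometryMismatchError(SecrError):
    """Two grids that must share a geometry do not."""


class PipelineError(SecrError):
    """A pipeline stage failed; message is prefixed with the stage name."""
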