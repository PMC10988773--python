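"""Exception hierarchy for the FPVS pipeline."""


class FPVSError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(FPVSError):
    """Invalid parameter combination (rates, bands, set sizes, ...)."""


class SchedulingError(FPVSError):
    """A stimulus stream or event schedule could not be constructed."""


class ValidationError(FPVSError):
    """Input data failed a structural or matching check."""


class SegmentationError(FPVSError):
    """An epoch window falls outside the recording."""


class FrequencyAlignmentError(FPVSError):
    """A requested frequency does not coincide with a spectral bin."""


class EdgeError(FPVSError):
    """A noise window extends past the edge of the spectrum."""
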