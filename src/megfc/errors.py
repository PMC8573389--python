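"""Exception types shared across the pipeline."""


class MegfcError(Exception):
    """Base class for package-specific errors."""


class SegmentUnavailableError(MegfcError):
    """A requested analysis segment cannot be placed inside the recording."""


class UndefinedCorrelationError(MegfcError):
    """Correlation requested for a zero-variance (flat) signal."""


class CollinearityError(MegfcError):
    """Covariate matrix is rank deficient; residualization is not identified."""


class DegenerateTestError(MegfcError):
    """A test statistic is undefined (e.g. zero-variance paired differences)."""
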