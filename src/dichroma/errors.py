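"""Exception hierarchy shared across the package."""


class DichromaError(Exception):
    """Base class for package errors."""


class SpectraFormatError(DichromaError, ValueError):
    """Malformed spectra file (non-monotone wavelengths, bad columns, NaNs)."""


class MetadataMismatchError(DichromaError, KeyError):
    """Spectra and metadata tables do not describe the same samples."""


class ParameterError(DichromaError, ValueError):
    """Invalid analysis parameter (span, Weber fraction, cone ratio, k, ...)."""


class DegenerateInputError(DichromaError, ValueError):
    """Input on which the quantity is mathematically undefined
    (zero quantum catch, empty locus set, single-sex region, ...)."""


class DegenerateRegionError(DichromaError, RuntimeError):
    """A body region left with too few samples to analyse."""


class RegionNotFoundError(DichromaError, KeyError):
    """Requested body region absent from the sample metadata."""
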