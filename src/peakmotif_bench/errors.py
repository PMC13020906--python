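"""Exception hierarchy shared across the package."""


class PeakMotifError(Exception):
    """Base class for all package errors."""


class FormatError(PeakMotifError):
    """A file does not conform to its declared dialect."""


class ValidationError(PeakMotifError):
    """Parsed values violate a domain invariant (e.g. end <= start)."""


class BoundsError(PeakMotifError):
    """A genomic interval falls outside its chromosome."""


class EmptyInputError(PeakMotifError):
    """An operation that requires data received an empty collection."""


class ConfigError(PeakMotifError):
    """A run configuration is inconsistent or incomplete."""


class DegenerateMotifError(PeakMotifError):
    """A motif matrix cannot be transformed as requested (e.g. zero cell
    with zero pseudocount, or a discovery seed absent from every sequence)."""


class InsufficientDataError(PeakMotifError):
    """Too few sequences/observations for the requested analysis."""


class PlacementError(PeakMotifError):
    """The synthetic generator cannot place features under the constraints."""
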