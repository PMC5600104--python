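"""Exception hierarchy shared across the package."""


class MRKineticsError(Exception):
    """Base class for all package errors."""


class FormatError(MRKineticsError):
    """Malformed input table (missing column, unparsable file)."""


class ValidationError(MRKineticsError):
    """Input values violate a documented invariant."""


class HarmonizationError(MRKineticsError):
    """Exposure/outcome alleles cannot be reconciled for a SNP."""


class DesignError(MRKineticsError):
    """Experimental design insufficient for the requested fit."""
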