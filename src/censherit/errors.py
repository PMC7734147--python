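"""Exception types shared across the package."""


class CensheritError(Exception):
    """Base class for all package errors."""


class PedigreeError(CensheritError):
    """Invalid pedigree structure (cycles, missing ancestors, duplicates)."""


class ValidationError(CensheritError):
    """Malformed or inconsistent input data."""


class DesignError(CensheritError):
    """Infeasible or inconsistent simulation design."""


class EstimabilityError(CensheritError):
    """A fixed-effect level has no supporting records."""
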