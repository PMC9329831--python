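"""Exception hierarchy shared across the package."""


class VldlcError(Exception):
    """Base class for all package-specific errors."""


class InvalidPanelError(VldlcError, ValueError):
    """A lipid panel violates a basic physical constraint (e.g. HDL-C > TC)."""


class DomainError(VldlcError, ValueError):
    """An input falls outside an equation's mathematical domain."""


class UndefinedRatioError(DomainError):
    """A ratio was requested with a zero denominator (e.g. VLDL-C/TG at TG = 0)."""


class MissingAnalyteError(VldlcError, ValueError):
    """A required analyte is absent (e.g. apoB for the enhanced equation)."""


class ConfigurationError(VldlcError):
    """A constants record or configuration is absent or unverified."""


class RankDeficientError(VldlcError, ValueError):
    """The regression design matrix is not full rank."""


class TooFewRecordsError(VldlcError, ValueError):
    """Fewer records than a fit or split requires."""


class CalibrationError(VldlcError, ValueError):
    """A distribution calibration target is degenerate or infeasible."""


class InfeasibleSpecError(VldlcError, RuntimeError):
    """Rejection sampling exceeded its retry budget for a cohort spec."""


class TableFormatError(VldlcError, ValueError):
    """A tabular input file is malformed (missing column, bad cell, bad units)."""
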