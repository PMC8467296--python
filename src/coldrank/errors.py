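"""Exception types shared across the pipeline."""


class ColdrankError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(ColdrankError):
    """A configuration value is out of range or inconsistent."""


class InvalidInputError(ColdrankError):
    """An input table or value set violates a precondition."""


class InsufficientDataError(ColdrankError):
    """Not enough observations to compute the requested quantity."""


class BalanceError(ColdrankError):
    """Breed-balanced extreme groups cannot be formed from the cohort."""


class UndefinedRatioError(ColdrankError):
    """A ratio statistic has a zero denominator (e.g. no transversions)."""


class DegenerateSampleError(ColdrankError):
    """Group sample sizes too small for the variance-component estimator."""


class MissingWindowError(ColdrankError):
    """A SNP position is covered by no computed window."""


class ParseError(ColdrankError):
    """A record or line in an input file could not be parsed."""


class ConsistencyError(ColdrankError):
    """Genome FASTA and annotation (or VCF) disagree at a position."""
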