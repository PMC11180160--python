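"""Exception hierarchy for the seedless package."""


class SeedlessError(Exception):
    """Base class for all package-specific errors."""


class ClassMismatchError(SeedlessError):
    """Observed classes and hypothesis classes do not line up."""


class UndefinedTestError(SeedlessError):
    """A test was requested on data that cannot support it (e.g. zero total)."""


class InvalidHypothesisError(SeedlessError):
    """A ratio hypothesis produces an expected count of zero."""


class ConfigurationError(SeedlessError):
    """Invalid or empty configuration (e.g. an empty hypothesis panel)."""


class InsufficientFamiliesError(SeedlessError):
    """A heterogeneity partition needs at least two families."""


class InvalidDistanceError(SeedlessError):
    """A map distance outside the supported (0, 50) cM range."""


class StructuralError(SeedlessError):
    """Inconsistent genomic structures (out-of-bounds alignment, overlapping anchors)."""


class AnchorError(SeedlessError):
    """A junction contig could not be anchored on the reference."""


class AmbiguousAnchorError(AnchorError):
    """A junction contig anchors at more than one reference locus."""


class ComparabilityError(SeedlessError):
    """Two deletion calls cannot be compared (different references)."""


class UnmatchedPlantError(SeedlessError):
    """Genotype and phenotype records could not be joined on plant id."""

    def __init__(self, offenders):
        self.offenders = sorted(offenders)
        super().__init__(f"unmatched plant ids: {', '.join(self.offenders)}")
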