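"""Mendelian segregation testing for cross families.

Goodness-of-fit of observed class counts (seeded/seedless phenotypes, or
codominant marker genotypes) against expected Mendelian ratios, plus the
classical pooled/heterogeneity chi-square partition across families:

    sum of per-family chi2  =  pooled chi2 (on summed counts)  +  heterogeneity chi2

The heterogeneity component tests whether the families share a common
segregation ratio; its degrees of freedom are (families - 1) x (classes - 1).

No continuity correction is applied anywhere: the uncorrected statistic is
the one that reproduces published plant-breeding segregation tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ClassMismatchError,
    ConfigurationError,
    InsufficientFamiliesError,
    InvalidHypothesisError,
    UndefinedTestError,
)
from .types import Generation

__all__ = [
    "CrossFamily",
    "RatioHypothesis",
    "ChiSquareResult",
    "FamilySetResult",
    "chi_square_gof",
    "test_hypothesis_panel",
    "heterogeneity_partition",
    "default_hypothesis_panel",
    "drop_structural_zeros",
    "read_family_table",
    "results_table",
]


@dataclass(frozen=True)
class CrossFamily:
    """Observed class counts for one cross family."""

    family_id: str
    generation: Generation
    class_labels: tuple[str, ...]
    observed: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "generation", Generation.coerce(self.generation))
        object.__setattr__(self, "class_labels", tuple(self.class_labels))
        object.__setattr__(self, "observed", tuple(int(x) for x in self.observed))
        if len(self.class_labels) < 1:
            raise ValueError("at least one class required")
        if len(self.observed) != len(self.class_labels):
            raise ValueError("observed counts and class labels differ in length")
        if any(x < 0 for x in self.observed):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.observed)


@dataclass(frozen=True)
class RatioHypothesis:
    """An expected segregation ratio, e.g. 3:1 -> ratio (3, 1).

    Ratio terms of zero are permitted at construction (printed hypotheses such
    as 1:1:0 contain structural zeros) but must be removed with
    :func:`drop_structural_zeros` before the chi-square test, which requires
    strictly positive expectations.
    """

    name: str
    gene_count: int
    ratio: tuple[float, ...]
    class_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ratio", tuple(float(r) for r in self.ratio))
        object.__setattr__(self, "class_labels", tuple(self.class_labels))
        if len(self.ratio) != len(self.class_labels):
            raise ValueError("ratio and class labels differ in length")
        if any(r < 0 for r in self.ratio):
            raise ValueError("ratio terms must be non-negative")
        if sum(self.ratio) == 0:
            raise ValueError("ratio must have a positive term")
        if not 1 <= int(self.gene_count) <= 3:
            raise ValueError("gene_count must be 1..3")

    @classmethod
    def from_string(cls, text: str, gene_count: int = 1,
                    class_labels: Sequence[str] | None = None) -> "RatioHypothesis":
        """Parse '3:1' / '1:2:1' style ratio strings."""
        terms = tuple(float(t) for t in text.split(":"))
        labels = tuple(class_labels) if class_labels else tuple(
            f"class_{i + 1}" for i in range(len(terms)))
        return cls(name=text, gene_count=gene_count, ratio=terms, class_labels=labels)

    def expected_counts(self, total: int) -> np.ndarray:
        r = np.asarray(self.ratio, dtype=float)
        return total * r / r.sum()


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    significant: bool
    alpha: float


@dataclass
class FamilySetResult:
    """Pooled/heterogeneity partition of per-family chi-square statistics."""

    per_family: list[ChiSquareResult] = field(default_factory=list)
    family_ids: list[str] = field(default_factory=list)
    total_statistic: float = 0.0
    pooled: ChiSquareResult | None = None
    heterogeneity: ChiSquareResult | None = None


def _check_compatible(family: CrossFamily, hypothesis: RatioHypothesis) -> None:
    if len(family.observed) != len(hypothesis.ratio):
        raise ClassMismatchError(
            f"family {family.family_id!r} has {len(family.observed)} classes, "
            f"hypothesis {hypothesis.name!r} has {len(hypothesis.ratio)}")


def chi_square_gof(family: CrossFamily, hypothesis: RatioHypothesis,
                   alpha: float = 0.05) -> ChiSquareResult:
    """Uncorrected chi-square goodness of fit of one family against a ratio.

    statistic = sum (O_i - E_i)^2 / E_i with E_i = total * ratio_i / sum(ratio),
    df = classes - 1, p from the upper tail of the chi-square distribution.
    A p-value exactly equal to alpha is called non-significant.
    """
    _check_compatible(family, hypothesis)
    if family.total == 0:
        raise UndefinedTestError(f"family {family.family_id!r} has zero total")
    expected = hypothesis.expected_counts(family.total)
    if np.any(expected == 0):
        raise InvalidHypothesisError(
            f"hypothesis {hypothesis.name!r} yields an expected count of zero; "
            "drop structural zeros first")
    observed = np.asarray(family.observed, dtype=float)
    statistic, p_value = stats.chisquare(observed, expected)
    statistic = float(statistic)
    # exact fit: clamp numerical dust so statistic==0 implies p==1
    if statistic < 1e-12:
        statistic, p_value = 0.0, 1.0
    df = len(family.observed) - 1
    return ChiSquareResult(statistic=statistic, df=df, p_value=float(p_value),
                           significant=bool(p_value < alpha), alpha=alpha)


def drop_structural_zeros(family: CrossFamily,
                          hypothesis: RatioHypothesis) -> tuple[CrossFamily, RatioHypothesis]:
    """Remove classes whose expected ratio term is zero (e.g. 1:1:0).

    Raises InvalidHypothesisError if any observed count in a zero-ratio class
    is nonzero: the hypothesis is then falsified structurally, not by chi2.
    """
    _check_compatible(family, hypothesis)
    keep = [i for i, r in enumerate(hypothesis.ratio) if r > 0]
    if len(keep) == len(hypothesis.ratio):
        return family, hypothesis
    for i, (obs, r) in enumerate(zip(family.observed, hypothesis.ratio)):
        if r == 0 and obs != 0:
            raise InvalidHypothesisError(
                f"class {family.class_labels[i]!r} expected absent under "
                f"{hypothesis.name!r} but observed {obs}")
    fam = CrossFamily(family.family_id, family.generation,
                      tuple(family.class_labels[i] for i in keep),
                      tuple(family.observed[i] for i in keep))
    hyp = RatioHypothesis(hypothesis.name, hypothesis.gene_count,
                          tuple(hypothesis.ratio[i] for i in keep),
                          tuple(hypothesis.class_labels[i] for i in keep))
    return fam, hyp


def test_hypothesis_panel(family: CrossFamily,
                          hypotheses: Sequence[RatioHypothesis],
                          alpha: float = 0.05) -> pd.DataFrame:
    """Test one family against a panel of ratio hypotheses.

    Returns a table (input order preserved) with one row per hypothesis and a
    ``rejected`` flag at the given alpha.
    """
    if len(hypotheses) == 0:
        raise ConfigurationError("empty hypothesis panel")
    rows = []
    for hyp in hypotheses:
        fam2, hyp2 = drop_structural_zeros(family, hyp)
        res = chi_square_gof(fam2, hyp2, alpha=alpha)
        rows.append({
            "hypothesis": hyp.name,
            "gene_count": hyp.gene_count,
            "statistic": res.statistic,
            "df": res.df,
            "p_value": res.p_value,
            "rejected": res.significant,
        })
    return pd.DataFrame(rows)


def heterogeneity_partition(families: Sequence[CrossFamily],
                            hypothesis: RatioHypothesis,
                            alpha: float = 0.05) -> FamilySetResult:
    """Partition summed per-family chi2 into pooled and heterogeneity parts.

    The pooled test is the goodness of fit of the element-wise sum of
    observed counts; heterogeneity = total - pooled with
    df = (families - 1) * (classes - 1).
    """
    if len(families) < 2:
        raise InsufficientFamiliesError("heterogeneity partition needs >= 2 families")
    per_family = [chi_square_gof(f, hypothesis, alpha=alpha) for f in families]
    total_statistic = float(sum(r.statistic for r in per_family))
    summed = tuple(int(s) for s in np.sum([f.observed for f in families], axis=0))
    pooled_family = CrossFamily("pooled", families[0].generation,
                                families[0].class_labels, summed)
    pooled = chi_square_gof(pooled_family, hypothesis, alpha=alpha)
    het_stat = max(0.0, total_statistic - pooled.statistic)
    het_df = (len(families) - 1) * (len(hypothesis.ratio) - 1)
    het_p = float(stats.chi2.sf(het_stat, het_df))
    heterogeneity = ChiSquareResult(statistic=het_stat, df=het_df, p_value=het_p,
                                    significant=bool(het_p < alpha), alpha=alpha)
    return FamilySetResult(per_family=per_family,
                           family_ids=[f.family_id for f in families],
                           total_statistic=total_statistic,
                           pooled=pooled, heterogeneity=heterogeneity)


def default_hypothesis_panel(gene_counts: Iterable[int] = (1, 2, 3),
                             class_labels: Sequence[str] = ("presence", "absence"),
                             ) -> list[RatioHypothesis]:
    """A stand-in panel of two-class segregation hypotheses for 1-3 genes.

    One gene: 3:1.  Two genes: 9:7, 13:3, 15:1 (complementary, recessive
    epistasis, duplicate dominant).  Three genes: 37:27, 63:1.  User code can
    always supply its own panel instead.
    """
    by_genes = {
        1: ["3:1"],
        2: ["9:7", "13:3", "15:1"],
        3: ["37:27", "63:1"],
    }
    panel = []
    for g in gene_counts:
        for text in by_genes.get(int(g), []):
            panel.append(RatioHypothesis.from_string(text, gene_count=int(g),
                                                     class_labels=class_labels))
    if not panel:
        raise ConfigurationError(f"no hypotheses for gene counts {list(gene_counts)}")
    return panel


def read_family_table(path) -> list[CrossFamily]:
    """Read families from delimited text.

    Columns: family_id, generation, labels, counts — the last two are
    ';'-separated and aligned.
    """
    df = pd.read_csv(path)
    required = {"family_id", "generation", "labels", "counts"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"family table missing columns: {sorted(missing)}")
    families = []
    for _, row in df.iterrows():
        labels = tuple(str(row["labels"]).split(";"))
        counts = tuple(int(c) for c in str(row["counts"]).split(";"))
        families.append(CrossFamily(str(row["family_id"]), row["generation"],
                                    labels, counts))
    return families


def results_table(families: Sequence[CrossFamily],
                  hypotheses: Sequence[RatioHypothesis],
                  alpha: float = 0.05) -> pd.DataFrame:
    """One row per family x hypothesis, mirroring published segregation tables."""
    rows = []
    for fam, hyp in itertools.product(families, hypotheses):
        fam2, hyp2 = drop_structural_zeros(fam, hyp)
        res = chi_square_gof(fam2, hyp2, alpha=alpha)
        rows.append({
            "family_id": fam.family_id,
            "generation": fam.generation.value,
            "observed": ":".join(str(o) for o in fam.observed),
            "expected_ratio": hyp.name,
            "chi2": res.statistic,
            "df": res.df,
            "p_value": res.p_value,
            "significance": "*" if res.significant else "ns",
        })
    return pd.DataFrame(rows)
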