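"""Cosegregation-based upper bound on marker-trait map distance.

With a fully recessive trait, a marker-trait recombination event is only
phenotypically visible on chromosomes transmitted through a heterozygous
parent in which the recombinant haplotype changes the phenotype class:

* F2 heterozygote: 1 informative chromosome (the wild-type-marker one);
* F2 homozygous mutant: both chromosomes (2);
* backcross-to-mutant (BC_Bs) progeny: 1 per plant (the F1-derived gamete);
* backcross-to-wild-type (BC_M) progeny: 0 — all carry a dominant allele
  from the recurrent parent and are seeded regardless of recombination.

If zero recombinants are seen among n informative chromosomes, a map
distance d (in cM) predicting E = n*d/100 recombinants can be rejected when
the chi-square term (O-E)^2/E exceeds the critical value, giving an upper
bound d* = 100 * chi2_crit(alpha, 1) / n on the marker-trait distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InvalidDistanceError, UndefinedTestError
from .types import Generation, Genotype, Phenotype

__all__ = [
    "ProgenyRecord",
    "InformativeCount",
    "DistanceBoundResult",
    "count_informative_chromosomes",
    "distance_rejection_test",
    "min_rejectable_distance",
    "recombination_power_mc",
    "read_progeny_table",
]

StatisticVariant = Literal["recombinant_class_term", "two_class"]

# informative chromosomes contributed per (generation, marker genotype)
_CONTRIBUTION: dict[tuple[Generation, Genotype], int] = {
    (Generation.F2, Genotype.HET): 1,
    (Generation.F2, Genotype.HOM_DEL): 2,
    (Generation.F2, Genotype.HOM_WT): 0,
    (Generation.BC_BS, Genotype.HET): 1,
    (Generation.BC_BS, Genotype.HOM_DEL): 1,
    (Generation.BC_BS, Genotype.HOM_WT): 0,
}


@dataclass(frozen=True)
class ProgenyRecord:
    plant_id: str
    generation: Generation
    genotype: Genotype
    phenotype: Phenotype

    def __post_init__(self) -> None:
        object.__setattr__(self, "generation", Generation.coerce(self.generation))
        object.__setattr__(self, "genotype", Genotype.coerce(self.genotype))
        object.__setattr__(self, "phenotype", Phenotype.coerce(self.phenotype))


@dataclass(frozen=True)
class InformativeCount:
    n_chromosomes: int
    n_recombinants_observed: int
    breakdown: pd.DataFrame  # rows: (generation, genotype) -> plants, chromosomes

    def __post_init__(self) -> None:
        if self.n_recombinants_observed > self.n_chromosomes:
            raise ValueError("more recombinants than informative chromosomes")


@dataclass(frozen=True)
class DistanceBoundResult:
    tested_distance_cM: float
    expected_recombinants: float
    statistic: float
    df: int
    p_value: float
    rejected: bool
    alpha: float
    statistic_variant: StatisticVariant


def _is_discordant(genotype: Genotype, phenotype: Phenotype) -> bool:
    """Genotype-phenotype mismatch under the fully recessive model."""
    if genotype in (Genotype.HOM_WT, Genotype.HET):
        return phenotype is Phenotype.SEEDLESS
    if genotype is Genotype.HOM_DEL:
        return phenotype is Phenotype.SEEDED
    return False


def count_informative_chromosomes(records: Iterable[ProgenyRecord]) -> InformativeCount:
    """Tally informative chromosomes and observed recombinants.

    Plants with no_call genotype or unknown phenotype are excluded.  A
    genotype-phenotype-discordant plant counts one observed recombinant
    chromosome (the minimum the discordance implies).
    """
    tallies: dict[tuple[Generation, Genotype], list[int]] = {}
    n_chrom = 0
    n_rec = 0
    for rec in records:
        if rec.genotype is Genotype.NO_CALL or rec.phenotype is Phenotype.UNKNOWN:
            continue
        contrib = _CONTRIBUTION.get((rec.generation, rec.genotype), 0)
        entry = tallies.setdefault((rec.generation, rec.genotype), [0, 0])
        entry[0] += 1
        entry[1] += contrib
        n_chrom += contrib
        if contrib > 0 and _is_discordant(rec.genotype, rec.phenotype):
            n_rec += 1
    breakdown = pd.DataFrame(
        [{"generation": g.value, "genotype": gt.value,
          "plants": v[0], "chromosomes": v[1]}
         for (g, gt), v in sorted(tallies.items(), key=lambda kv: (kv[0][0].value,
                                                                   kv[0][1].value))]
    )
    return InformativeCount(n_chromosomes=n_chrom, n_recombinants_observed=n_rec,
                            breakdown=breakdown)


def _statistic(o_rec: float, n: float, d_cM: float,
               variant: StatisticVariant) -> tuple[float, float]:
    e_rec = n * d_cM / 100.0
    if e_rec <= 0:
        raise InvalidDistanceError("expected recombinant count is zero")
    stat = (o_rec - e_rec) ** 2 / e_rec
    if variant == "two_class":
        e_non = n - e_rec
        stat += (n - o_rec - e_non) ** 2 / e_non
    elif variant != "recombinant_class_term":
        raise ConfigurationError(f"unknown statistic variant {variant!r}")
    return stat, e_rec


def distance_rejection_test(count: InformativeCount, distance_cM: float,
                            alpha: float = 0.05,
                            variant: StatisticVariant = "recombinant_class_term",
                            ) -> DistanceBoundResult:
    """Chi-square test of observed recombinants against a candidate distance.

    The default recombinant-class statistic uses only the recombinant-class
    term (O-E)^2/E at df 1; ``two_class`` adds the non-recombinant term.
    With O = 0, the default statistic equals the expected recombinant count
    n*d/100 exactly.
    """
    if count.n_chromosomes <= 0:
        raise UndefinedTestError("no informative chromosomes")
    if not 0 < distance_cM < 50:
        raise InvalidDistanceError("distance must be in (0, 50) cM")
    stat, e_rec = _statistic(count.n_recombinants_observed, count.n_chromosomes,
                             distance_cM, variant)
    p = float(stats.chi2.sf(stat, 1))
    return DistanceBoundResult(tested_distance_cM=float(distance_cM),
                               expected_recombinants=e_rec, statistic=float(stat),
                               df=1, p_value=p, rejected=bool(p < alpha),
                               alpha=alpha, statistic_variant=variant)


def min_rejectable_distance(count: InformativeCount, alpha: float = 0.05,
                            variant: StatisticVariant = "recombinant_class_term",
                            ) -> float | None:
    """Smallest map distance (cM) rejectable at ``alpha`` given the data.

    With zero observed recombinants and the recombinant-class statistic the
    closed form is d* = 100 * chi2_crit(alpha, 1) / n; otherwise the boundary
    is found by bisection on the distance.  Returns None when no distance
    below 50 cM can be rejected.  The returned value is the infimum: the test
    statistic sits exactly on the critical value there, and any strictly
    larger distance is rejected.
    """
    n = count.n_chromosomes
    if n <= 0:
        raise UndefinedTestError("no informative chromosomes")
    crit = float(stats.chi2.ppf(1 - alpha, 1))

    if count.n_recombinants_observed == 0 and variant == "recombinant_class_term":
        d = 100.0 * crit / n
        return d if d < 50 else None

    def excess(d: float) -> float:
        stat, _ = _statistic(count.n_recombinants_observed, n, d, variant)
        return stat - crit

    # the statistic is zero at the point estimate and increases beyond it
    d_hat = 100.0 * count.n_recombinants_observed / n
    lo = max(d_hat, 1e-9)
    hi = 50.0 - 1e-9
    if excess(hi) <= 0:
        return None
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if excess(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def recombination_power_mc(n: int, d_cM: float, alpha: float = 0.05,
                           reps: int = 10_000, seed: int = 0,
                           test_distance_cM: float | None = None,
                           variant: StatisticVariant = "recombinant_class_term",
                           ) -> float:
    """Monte Carlo rejection probability of the distance test.

    Simulates binomial recombinant counts at true rate ``d_cM``/100 over ``n``
    chromosomes and applies the rejection test at ``test_distance_cM``
    (defaults to the true distance, which estimates the type-I error).
    """
    if reps < 1:
        raise ConfigurationError("reps must be >= 1")
    if n <= 0:
        raise UndefinedTestError("no informative chromosomes")
    test_d = d_cM if test_distance_cM is None else test_distance_cM
    if not 0 < test_d < 50:
        raise InvalidDistanceError("tested distance must be in (0, 50) cM")
    rng = np.random.default_rng(seed)
    o = rng.binomial(n, d_cM / 100.0, size=reps).astype(float)
    e = n * test_d / 100.0
    stat = (o - e) ** 2 / e
    if variant == "two_class":
        stat += (o - e) ** 2 / (n - e)
    p = stats.chi2.sf(stat, 1)
    return float(np.mean(p < alpha))


def read_progeny_table(path) -> list[ProgenyRecord]:
    """Read progeny records (plant_id, generation, genotype, phenotype) from CSV."""
    df = pd.read_csv(path)
    required = {"plant_id", "generation", "genotype", "phenotype"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"progeny table missing columns: {sorted(missing)}")
    return [ProgenyRecord(str(r["plant_id"]), r["generation"], r["genotype"],
                          r["phenotype"]) for _, r in df.iterrows()]
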