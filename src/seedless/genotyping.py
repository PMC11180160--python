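"""Codominant and dominant PCR-marker genotype calls at the *INO* locus.

The codominant assay combines a wild-type-specific product (~350 bp, from
primers inside the *INO* gene) with a deletion-junction-specific product
(the AsINODel-style amplicon): heterozygotes show both bands.  Band calling
consumes boolean band presence scored from a gel, not images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd

from .errors import UnmatchedPlantError
from .linkage import ProgenyRecord
from .types import Generation, Genotype, Phenotype

__all__ = [
    "BandPattern",
    "DominantCall",
    "CosegregationSummary",
    "call_codominant",
    "call_dominant",
    "cosegregation_analysis",
    "read_band_table",
    "genotype_table",
]


@dataclass(frozen=True)
class BandPattern:
    """Presence/absence of the two diagnostic PCR products for one plant."""

    plant_id: str
    wt_band: bool
    del_band: bool


class DominantCall(str, Enum):
    CARRIES_INO = "carries_INO"          # hom_wt or het, unresolved
    PUTATIVE_HOM_DEL = "putative_hom_del"  # absence-based inference


@dataclass
class CosegregationSummary:
    counts: pd.DataFrame            # genotype x phenotype contingency table
    n_scored: int
    n_concordant: int
    n_discordant: int
    discordant_plants: list[str] = field(default_factory=list)
    no_call_plants: list[str] = field(default_factory=list)


_CODOMINANT_MAP = {
    (True, False): Genotype.HOM_WT,
    (True, True): Genotype.HET,
    (False, True): Genotype.HOM_DEL,
    (False, False): Genotype.NO_CALL,
}


def call_codominant(pattern: BandPattern) -> Genotype:
    """Map a band pattern to a genotype; (no band, no band) is a no-call."""
    return _CODOMINANT_MAP[(pattern.wt_band, pattern.del_band)]


def call_dominant(has_wt_band: bool) -> DominantCall:
    """Dominant (wild-type-only) assay: absence of product is only an
    absence-based inference of homozygosity for the deletion."""
    return DominantCall.CARRIES_INO if has_wt_band else DominantCall.PUTATIVE_HOM_DEL


def _is_discordant(genotype: Genotype, phenotype: Phenotype) -> bool:
    if genotype in (Genotype.HOM_WT, Genotype.HET):
        return phenotype is Phenotype.SEEDLESS
    if genotype is Genotype.HOM_DEL:
        return phenotype is Phenotype.SEEDED
    return False


def cosegregation_analysis(genotypes: Mapping[str, Genotype],
                           phenotypes: Mapping[str, Phenotype | str],
                           ) -> CosegregationSummary:
    """Cross-tabulate genotype calls against seed phenotypes.

    A discordant plant carries a wild-type allele yet is seedless, or is
    homozygous for the deletion yet seeded.  No-call genotypes and unknown
    phenotypes are excluded from the table and listed separately.  Plant ids
    present in one mapping but not the other raise UnmatchedPlantError.
    """
    unmatched = set(genotypes) ^ set(phenotypes)
    if unmatched:
        raise UnmatchedPlantError(unmatched)
    geno_levels = [Genotype.HOM_WT, Genotype.HET, Genotype.HOM_DEL]
    pheno_levels = [Phenotype.SEEDED, Phenotype.SEEDLESS]
    counts = pd.DataFrame(0, index=[g.value for g in geno_levels],
                          columns=[p.value for p in pheno_levels])
    discordant, no_call = [], []
    n_scored = n_conc = n_disc = 0
    for plant_id in sorted(genotypes):
        g = Genotype.coerce(genotypes[plant_id])
        p = Phenotype.coerce(phenotypes[plant_id])
        if g is Genotype.NO_CALL or p is Phenotype.UNKNOWN:
            no_call.append(plant_id)
            continue
        counts.loc[g.value, p.value] += 1
        n_scored += 1
        if _is_discordant(g, p):
            n_disc += 1
            discordant.append(plant_id)
        else:
            n_conc += 1
    return CosegregationSummary(counts=counts, n_scored=n_scored,
                                n_concordant=n_conc, n_discordant=n_disc,
                                discordant_plants=discordant,
                                no_call_plants=no_call)


def read_band_table(path) -> list[BandPattern]:
    """Read a delimited band table: plant_id, wt_band, del_band (0/1)."""
    df = pd.read_csv(path)
    return [BandPattern(str(r["plant_id"]), bool(int(r["wt_band"])),
                        bool(int(r["del_band"]))) for _, r in df.iterrows()]


def genotype_table(patterns: Sequence[BandPattern],
                   generation: Generation | str = Generation.F2,
                   phenotypes: Mapping[str, Phenotype | str] | None = None,
                   ) -> pd.DataFrame:
    """Genotype calls as a table consumable by the segregation and linkage
    analyses (columns plant_id, generation, genotype, phenotype)."""
    generation = Generation.coerce(generation)
    rows = []
    for pat in patterns:
        geno = call_codominant(pat)
        pheno = Phenotype.UNKNOWN
        if phenotypes is not None and pat.plant_id in phenotypes:
            pheno = Phenotype.coerce(phenotypes[pat.plant_id])
        rows.append({"plant_id": pat.plant_id, "generation": generation.value,
                     "genotype": geno.value, "phenotype": pheno.value})
    return pd.DataFrame(rows)


def to_progeny_records(table: pd.DataFrame) -> list[ProgenyRecord]:
    """Convert a genotype table into linkage-analysis progeny records."""
    return [ProgenyRecord(str(r["plant_id"]), r["generation"], r["genotype"],
                          r["phenotype"]) for _, r in table.iterrows()]
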