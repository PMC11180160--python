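"""Published segregation-count tables for the sugar-apple seedless trait.

These are the printed observed counts for the crosses between the fertile
wild-type parents (M1, M2, M3) and the Brazilian seedless mutant (Bs):
phenotypic seed counts, dominant-marker (wild-type-product presence/absence)
counts, and codominant genotype counts at the *INO* locus.  They are data,
small enough to ship as code, and are the inputs of the reproduction
analyses.

The per-plant genotype/phenotype split behind the 114 informative
chromosomes is not published at plant level; ``informative_progeny_records``
returns a synthetic reconstruction consistent with the published totals
(57 heterozygous plants, 36 homozygous mutants — of which 21 F2 plants and
15 backcross-to-mutant plants — all phenotype-concordant).
"""

from __future__ import annotations

from .cross_genetics import CrossFamily, RatioHypothesis
from .linkage import ProgenyRecord
from .types import Generation, Genotype, Phenotype

__all__ = [
    "RATIO_3_1",
    "RATIO_1_1",
    "RATIO_1_2_1",
    "RATIO_1_1_0",
    "RATIO_0_1_1",
    "phenotype_f2_family",
    "phenotype_bc_mut_family",
    "dominant_f2_families",
    "dominant_bc_mut_families",
    "codominant_families",
    "informative_progeny_records",
]

_PHENO = ("presence", "absence")
_GENO = ("INO INO", "INO ino", "ino ino")

RATIO_3_1 = RatioHypothesis("3:1", 1, (3, 1), _PHENO)
RATIO_1_1 = RatioHypothesis("1:1", 1, (1, 1), _PHENO)
RATIO_1_2_1 = RatioHypothesis("1:2:1", 1, (1, 2, 1), _GENO)
RATIO_1_1_0 = RatioHypothesis("1:1:0", 1, (1, 1, 0), _GENO)
RATIO_0_1_1 = RatioHypothesis("0:1:1", 1, (0, 1, 1), _GENO)


def phenotype_f2_family() -> CrossFamily:
    """Seed presence/absence in the M2-family F2 (48 seeded : 10 seedless)."""
    return CrossFamily("M2_F2_phenotype", Generation.F2, _PHENO, (48, 10))


def phenotype_bc_mut_family() -> CrossFamily:
    """Seed presence/absence in the M2-family backcross to the mutant (8:6)."""
    return CrossFamily("M2_BCBs_phenotype", Generation.BC_BS, _PHENO, (8, 6))


def dominant_f2_families() -> list[CrossFamily]:
    """Dominant-marker presence/absence in the three F2 families."""
    return [
        CrossFamily("M1_F2", Generation.F2, _PHENO, (99, 43)),
        CrossFamily("M2_F2", Generation.F2, _PHENO, (190, 71)),
        CrossFamily("M3_F2", Generation.F2, _PHENO, (69, 33)),
    ]


def dominant_bc_mut_families() -> list[CrossFamily]:
    """Dominant-marker presence/absence in the three backcrosses to Bs."""
    return [
        CrossFamily("M1_BCBs", Generation.BC_BS, _PHENO, (48, 61)),
        CrossFamily("M2_BCBs", Generation.BC_BS, _PHENO, (57, 59)),
        CrossFamily("M3_BCBs", Generation.BC_BS, _PHENO, (26, 30)),
    ]


def codominant_families() -> list[tuple[CrossFamily, RatioHypothesis]]:
    """Codominant genotype counts with their expected ratios (M2 family)."""
    return [
        (CrossFamily("M2_F2_codominant", Generation.F2, _GENO, (34, 70, 41)),
         RATIO_1_2_1),
        (CrossFamily("M2_BCM_codominant", Generation.BC_M, _GENO, (30, 26, 0)),
         RATIO_1_1_0),
        (CrossFamily("M2_BCBs_codominant", Generation.BC_BS, _GENO, (0, 30, 31)),
         RATIO_0_1_1),
    ]


def informative_progeny_records() -> list[ProgenyRecord]:
    """Synthetic per-plant reconstruction of the cosegregation data set.

    57 heterozygous F2 plants (1 informative chromosome each), 21 homozygous
    mutant F2 plants (2 each) and 15 homozygous mutant backcross-to-mutant
    plants (1 each): 114 informative chromosomes, zero observed recombinants.
    """
    records = []
    for i in range(57):
        records.append(ProgenyRecord(f"F2_het_{i + 1:03d}", Generation.F2,
                                     Genotype.HET, Phenotype.SEEDED))
    for i in range(21):
        records.append(ProgenyRecord(f"F2_del_{i + 1:03d}", Generation.F2,
                                     Genotype.HOM_DEL, Phenotype.SEEDLESS))
    for i in range(15):
        records.append(ProgenyRecord(f"BCBs_del_{i + 1:03d}", Generation.BC_BS,
                                     Genotype.HOM_DEL, Phenotype.SEEDLESS))
    return records
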