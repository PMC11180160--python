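"""Synthetic inputs emulating the study's field populations and sequencing.

Crosses use a single-chromosome, two-locus gamete model: a codominant
marker locus (the *INO* deletion assay) and the trait locus, separated by a
configurable map distance d; heterozygous parents emit recombinant gametes
with probability d/100 (no interference, single interval — adequate below
50 cM).  Seedlessness is fully recessive at the trait locus.

Read alignments are produced by truth projection rather than by running a
mapper: the deletion interval between the wild-type reference and the
sampled allele is known, so every read's reference placement follows by
coordinate arithmetic.  Reads spanning the deletion junction align to their
longer side with the remainder soft-clipped, which is exactly the boundary
signal the deletion caller consumes.  All generators are pure functions of
their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .deletion import AlignedRead, DeletionCall, ReferenceSeq
from .linkage import ProgenyRecord
from .ssr import BandMatrix
from .types import Generation, Genotype, Phenotype

__all__ = [
    "CrossSpec",
    "GenomeSpec",
    "ProgenyTable",
    "simulate_cross",
    "simulate_genome_pair",
    "simulate_alignments",
    "simulate_band_matrix",
]

_GENOTYPE_BY_DOSE = (Genotype.HOM_WT, Genotype.HET, Genotype.HOM_DEL)
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class CrossSpec:
    generation: Generation
    n_progeny: int
    marker_trait_distance_cM: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "generation", Generation.coerce(self.generation))
        if self.n_progeny < 1:
            raise ValueError("n_progeny must be >= 1")
        if not 0 <= self.marker_trait_distance_cM < 50:
            raise ValueError("distance must be in [0, 50) cM")


@dataclass(frozen=True)
class GenomeSpec:
    ref_length: int
    deletion_interval: tuple[int, int]
    gc_fraction: float = 0.4
    seed: int = 0
    margin: int = 1000

    def __post_init__(self) -> None:
        s, e = self.deletion_interval
        if not (self.margin <= s < e <= self.ref_length - self.margin):
            raise ValueError("deletion interval must lie strictly inside "
                             f"[{self.margin}, {self.ref_length - self.margin})")
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0, 1)")


class ProgenyTable:
    """Simulated progeny with true haplotypes, backed by numpy arrays.

    ``marker_dose`` / ``trait_dose`` count deletion alleles (0, 1, 2) at each
    locus; ``recombinant_gametes`` counts the recombinant gametes each plant
    received from heterozygous parents (for recombination-fraction checks).
    """

    def __init__(self, generation: Generation, marker_dose: np.ndarray,
                 trait_dose: np.ndarray, recombinant_gametes: np.ndarray,
                 n_meioses_per_plant: int):
        self.generation = generation
        self.marker_dose = marker_dose
        self.trait_dose = trait_dose
        self.recombinant_gametes = recombinant_gametes
        self.n_meioses_per_plant = n_meioses_per_plant

    def __len__(self) -> int:
        return len(self.marker_dose)

    def __iter__(self) -> Iterator[ProgenyRecord]:
        gen = self.generation
        for i in range(len(self)):
            yield ProgenyRecord(
                plant_id=f"{gen.value}_{i + 1:06d}",
                generation=gen,
                genotype=_GENOTYPE_BY_DOSE[self.marker_dose[i]],
                phenotype=(Phenotype.SEEDLESS if self.trait_dose[i] == 2
                           else Phenotype.SEEDED))

    def records(self) -> list[ProgenyRecord]:
        return list(self)

    def genotype_counts(self) -> dict[Genotype, int]:
        counts = np.bincount(self.marker_dose, minlength=3)
        return {g: int(c) for g, c in zip(_GENOTYPE_BY_DOSE, counts)}

    def phenotype_counts(self) -> dict[Phenotype, int]:
        seedless = int(np.sum(self.trait_dose == 2))
        return {Phenotype.SEEDED: len(self) - seedless,
                Phenotype.SEEDLESS: seedless}

    def recombinant_gamete_fraction(self) -> float:
        total = self.n_meioses_per_plant * len(self)
        if total == 0:
            return float("nan")
        return float(self.recombinant_gametes.sum()) / total

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "plant_id": [f"{self.generation.value}_{i + 1:06d}"
                         for i in range(len(self))],
            "generation": self.generation.value,
            "genotype": [_GENOTYPE_BY_DOSE[d].value for d in self.marker_dose],
            "phenotype": [Phenotype.SEEDLESS.value if d == 2
                          else Phenotype.SEEDED.value for d in self.trait_dose],
            "marker_dose": self.marker_dose,
            "trait_dose": self.trait_dose,
        })


def _het_gametes(rng: np.random.Generator, n: int, r: float
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gametes from an F1 (marker-del coupled with trait-mut): returns
    (marker allele, trait allele, recombinant flag), alleles coded 1=mutant."""
    hap = rng.integers(0, 2, size=n)          # parental haplotype choice
    rec = rng.random(n) < r                   # crossover between the loci
    marker = hap
    trait = np.where(rec, 1 - hap, hap)
    return marker, trait, rec.astype(np.int64)


def simulate_cross(spec: CrossSpec) -> ProgenyTable:
    """Simulate one cross family under the two-locus gamete model.

    Parents are homozygous lines: wild-type (INO, seeded) and the seedless
    mutant; F1 plants are coupling-phase double heterozygotes.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_progeny
    r = spec.marker_trait_distance_cM / 100.0
    if spec.generation is Generation.F1:
        marker = np.ones(n, dtype=np.int64)
        trait = np.ones(n, dtype=np.int64)
        rec = np.zeros(n, dtype=np.int64)
        return ProgenyTable(spec.generation, marker, trait, rec, 0)
    if spec.generation is Generation.F2:
        m1, t1, r1 = _het_gametes(rng, n, r)
        m2, t2, r2 = _het_gametes(rng, n, r)
        return ProgenyTable(spec.generation, m1 + m2, t1 + t2, r1 + r2, 2)
    m1, t1, r1 = _het_gametes(rng, n, r)
    if spec.generation is Generation.BC_M:    # recurrent parent wild-type
        other = np.zeros(n, dtype=np.int64)
    else:                                      # BC_Bs: recurrent parent mutant
        other = np.ones(n, dtype=np.int64)
    return ProgenyTable(spec.generation, m1 + other, t1 + other, r1, 1)


def _random_sequence(rng: np.random.Generator, length: int,
                     gc_fraction: float) -> str:
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    codes = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    return _BASES[codes].tobytes().decode()


def simulate_genome_pair(spec: GenomeSpec
                         ) -> tuple[ReferenceSeq, str, DeletionCall]:
    """Random wild-type reference, its deletion allele, and the truth call.

    The truth interval is reported left-aligned (random flanks can carry
    identical bases, shifting the canonical breakpoint slightly leftward of
    the interval that was excised).
    """
    rng = np.random.default_rng(spec.seed)
    ref_seq = _random_sequence(rng, spec.ref_length, spec.gc_fraction)
    s, e = spec.deletion_interval
    allele = ref_seq[:s] + ref_seq[e:]
    while s > 0 and ref_seq[s - 1] == ref_seq[e - 1]:
        s -= 1
        e -= 1
    reference = ReferenceSeq(name=f"synthetic_ref_{spec.seed}", sequence=ref_seq)
    truth = DeletionCall(reference_name=reference.name,
                         deleted_interval=(s, e), inserted_sequence="",
                         microhomology_len=0, classification="clean")
    return reference, allele, truth


def _infer_deletion(allele: str, reference: ReferenceSeq) -> tuple[int, int]:
    """Left-aligned interval deleted from the reference in ``allele``.

    Assumes the allele is the reference minus one contiguous interval (or
    identical to it, returning an empty interval).
    """
    ref = reference.sequence
    del_len = len(ref) - len(allele)
    if del_len < 0:
        raise ValueError("allele longer than reference")
    lcp = 0
    limit = len(allele)
    while lcp < limit and allele[lcp] == ref[lcp]:
        lcp += 1
    return lcp, lcp + del_len


def simulate_alignments(allele: str, reference: ReferenceSeq,
                        read_len: int = 150, depth: float = 20.0,
                        error_rate: float = 0.0, seed: int = 0,
                        ) -> list[AlignedRead]:
    """Uniform single-end reads from ``allele``, projected onto the reference.

    Reads contained in a retained segment align end-to-end; reads spanning
    the deletion junction are split there and aligned to their longer side
    with the remainder soft-clipped (ties keep the left side).  Substitution
    errors are injected at ``error_rate`` per base.
    """
    if read_len >= len(allele):
        raise ValueError("read length must be shorter than the allele")
    rng = np.random.default_rng(seed)
    n_reads = int(round(depth * len(allele) / read_len))
    if n_reads == 0:
        return []
    ds, de = _infer_deletion(allele, reference)
    shift = de - ds
    starts = np.sort(rng.integers(0, len(allele) - read_len + 1, size=n_reads))
    reads: list[AlignedRead] = []
    for i, start in enumerate(starts):
        seq = allele[start:start + read_len]
        if error_rate > 0:
            mask = rng.random(read_len) < error_rate
            if mask.any():
                arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
                for j in np.flatnonzero(mask):
                    choices = _BASES[_BASES != arr[j]]
                    arr[j] = rng.choice(choices)
                seq = arr.tobytes().decode()
        end = start + read_len
        if shift == 0 or end <= ds:
            ref_start, pre, suf = int(start), 0, 0
        elif start >= ds:
            ref_start, pre, suf = int(start + shift), 0, 0
        else:
            left = ds - start
            right = read_len - left
            if left >= right:
                ref_start, pre, suf = int(start), 0, int(right)
            else:
                ref_start, pre, suf = int(de), int(left), 0
        reads.append(AlignedRead(read_id=f"sim_{i:06d}", ref_start=ref_start,
                                 sequence=seq, clipped_prefix_len=pre,
                                 clipped_suffix_len=suf))
    return reads


def simulate_band_matrix(n_genotypes: int, n_monomorphic: int,
                         n_polymorphic: int, seed: int = 0) -> BandMatrix:
    """Binary SSR band matrix: constant monomorphic columns (all present),
    non-constant polymorphic columns."""
    if min(n_genotypes, 0) < 0 or n_monomorphic < 0 or n_polymorphic < 0:
        raise ValueError("counts must be non-negative")
    if n_genotypes < 2 and n_polymorphic > 0:
        raise ValueError("polymorphic bands need at least two genotypes")
    rng = np.random.default_rng(seed)
    cols = [np.ones(n_genotypes, dtype=np.int8)] * n_monomorphic
    poly_cols = []
    for _ in range(n_polymorphic):
        col = rng.integers(0, 2, size=n_genotypes).astype(np.int8)
        while col.min() == col.max():
            col = rng.integers(0, 2, size=n_genotypes).astype(np.int8)
        poly_cols.append(col)
    matrix = np.column_stack(cols + poly_cols) if (cols or poly_cols) else \
        np.zeros((n_genotypes, 0), dtype=np.int8)
    ids = tuple(f"genotype_{i + 1}" for i in range(n_genotypes))
    bands = tuple([f"mono_{i + 1}" for i in range(n_monomorphic)]
                  + [f"poly_{i + 1}" for i in range(n_polymorphic)])
    return BandMatrix(genotype_ids=ids, locus_band_ids=bands, matrix=matrix)
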