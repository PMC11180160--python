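"""Jaccard similarity on binary SSR (microsatellite) band matrices.

Bands are scored 1 (presence) / 0 (absence) per genotype.  The Jaccard
coefficient J = a / (a + b + c) counts shared presences (a) against
asymmetric presences (b, c); joint absences carry no information and are
excluded.  Distance = 1 - J.  A pair with no band present in either
genotype has an undefined similarity and is flagged rather than coerced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BandMatrix",
    "JaccardResult",
    "PolymorphismSummary",
    "jaccard_distance_matrix",
    "polymorphism_summary",
    "read_band_matrix",
    "pair_list",
]


@dataclass(frozen=True)
class BandMatrix:
    """Genotypes x band loci binary matrix."""

    genotype_ids: tuple[str, ...]
    locus_band_ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.int8)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "genotype_ids", tuple(self.genotype_ids))
        object.__setattr__(self, "locus_band_ids", tuple(self.locus_band_ids))
        if m.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if m.shape != (len(self.genotype_ids), len(self.locus_band_ids)):
            raise ValueError("matrix shape does not match id lists")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("matrix entries must be 0 or 1")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "BandMatrix":
        return cls(tuple(str(i) for i in df.index),
                   tuple(str(c) for c in df.columns), df.to_numpy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.genotype_ids),
                            columns=list(self.locus_band_ids))


@dataclass
class JaccardResult:
    distances: pd.DataFrame                    # symmetric, 0 diagonal, NaN if undefined
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)


@dataclass(frozen=True)
class PolymorphismSummary:
    n_bands: int
    n_amplified: int       # bands present in at least one genotype
    n_monomorphic: int     # constant across genotypes (all present or all absent)
    n_polymorphic: int
    band_class: pd.Series = None  # per-band 'monomorphic'/'polymorphic'


def jaccard_distance_matrix(m: BandMatrix) -> JaccardResult:
    """Pairwise Jaccard distances 1 - a/(a+b+c); joint absences excluded."""
    if len(m.genotype_ids) < 2:
        raise ValueError("need at least two genotypes")
    x = m.matrix.astype(np.int64)
    shared = x @ x.T                       # a
    row = x.sum(axis=1)
    union = row[:, None] + row[None, :] - shared  # a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = 1.0 - shared / union
    undefined = []
    n = len(m.genotype_ids)
    for i in range(n):
        for j in range(i + 1, n):
            if union[i, j] == 0:
                undefined.append((m.genotype_ids[i], m.genotype_ids[j]))
    np.fill_diagonal(dist, 0.0)
    df = pd.DataFrame(dist, index=list(m.genotype_ids),
                      columns=list(m.genotype_ids))
    return JaccardResult(distances=df, undefined_pairs=undefined)


def polymorphism_summary(m: BandMatrix) -> PolymorphismSummary:
    """Classify each band locus as monomorphic (constant) or polymorphic."""
    x = m.matrix
    present = x.sum(axis=0)
    n = x.shape[0]
    mono = (present == 0) | (present == n)
    classes = pd.Series(np.where(mono, "monomorphic", "polymorphic"),
                        index=list(m.locus_band_ids))
    return PolymorphismSummary(n_bands=x.shape[1],
                               n_amplified=int((present > 0).sum()),
                               n_monomorphic=int(mono.sum()),
                               n_polymorphic=int((~mono).sum()),
                               band_class=classes)


def pair_list(result: JaccardResult) -> pd.DataFrame:
    """Long-format genotype-pair distances (upper triangle)."""
    ids = list(result.distances.index)
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            d = result.distances.loc[a, b]
            rows.append({"genotype_a": a, "genotype_b": b,
                         "jaccard_distance": d,
                         "defined": not np.isnan(d)})
    return pd.DataFrame(rows)


def read_band_matrix(path) -> BandMatrix:
    """Read a delimited binary matrix, genotypes in rows, bands in columns."""
    df = pd.read_csv(path, index_col=0)
    return BandMatrix.from_dataframe(df)
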