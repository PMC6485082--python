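"""Stage 1: uncorrected p-distance screening of candidate population pairs.

Uncorrected p-distances on the mitochondrial locus are compared against the
amphibian barcoding band of 3-5%: non-conspecific pairs whose divergence falls
below the band are candidates for lumping, conspecific pairs above the band are
candidates for splitting, and pairs whose divergence range overlaps the band
fall in a reported grey zone that is never acted on automatically.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import CANONICAL_BASES, AlignedLocus, PopulationMap

__all__ = [
    "DistanceMatrix",
    "CandidatePair",
    "UndefinedDistanceError",
    "p_distance",
    "pairwise_matrix",
    "between_population_summary",
    "screen_candidates",
]

DEFAULT_LOWER_PCT = 3.0
DEFAULT_UPPER_PCT = 5.0


class UndefinedDistanceError(ValueError):
    """No comparable (unambiguous, ungapped) sites between two sequences."""


def p_distance(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Uncorrected p-distance between two aligned sequences.

    A site is comparable iff both symbols are unambiguous bases (A, C, G, T);
    gaps and IUPAC ambiguity codes are excluded pairwise.  Returns the
    proportion of mismatches among comparable sites and the comparable-site
    count.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequences differ in length ({len(seq_a)} vs {len(seq_b)})"
        )
    comparable = 0
    mismatch = 0
    for x, y in zip(seq_a, seq_b):
        if x in CANONICAL_BASES and y in CANONICAL_BASES:
            comparable += 1
            if x != y:
                mismatch += 1
    if comparable == 0:
        raise UndefinedDistanceError("zero comparable sites between sequences")
    return mismatch / comparable, comparable


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise p-distances with comparable-site counts."""

    samples: tuple[str, ...]
    values: np.ndarray          # proportions in [0, 1]
    comparable_sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.samples)
        v = np.asarray(self.values, dtype=float)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if (v < 0).any() or (v > 1).any():
            raise ValueError("p-distances must lie in [0, 1]")

    def distance(self, a: str, b: str) -> float:
        i, j = self.samples.index(a), self.samples.index(b)
        return float(self.values[i, j])


def pairwise_matrix(locus: AlignedLocus) -> DistanceMatrix:
    """All-pairs uncorrected p-distances (pairwise deletion) for one locus."""
    n = locus.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    # encode: 0..3 = ACGT, -1 = non-comparable symbol
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    enc = np.stack(
        [lut[np.frombuffer(s.encode(), dtype=np.uint8)] for s in locus.sequences]
    )
    ok = enc >= 0
    values = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=np.int64)
    for i, j in itertools.combinations(range(n), 2):
        both = ok[i] & ok[j]
        c = int(both.sum())
        if c == 0:
            raise UndefinedDistanceError(
                f"zero comparable sites between {locus.samples[i]!r} "
                f"and {locus.samples[j]!r}"
            )
        d = int((enc[i][both] != enc[j][both]).sum()) / c
        values[i, j] = values[j, i] = d
        sites[i, j] = sites[j, i] = c
    np.fill_diagonal(sites, locus.length)
    return DistanceMatrix(tuple(locus.samples), values, sites)


def between_population_summary(
    matrix: DistanceMatrix,
    popmap: PopulationMap,
    a: str,
    b: str,
) -> tuple[float, float, float]:
    """Min/max/mean p-distance over all cross-population pairs, in percent."""
    idx = {s: i for i, s in enumerate(matrix.samples)}
    ia = [idx[s] for s in popmap.samples_of(a) if s in idx]
    ib = [idx[s] for s in popmap.samples_of(b) if s in idx]
    if not ia or not ib:
        raise ValueError(f"no samples in the matrix for pair ({a!r}, {b!r})")
    cross = matrix.values[np.ix_(ia, ib)].ravel()
    return (
        float(cross.min()) * 100.0,
        float(cross.max()) * 100.0,
        float(cross.mean()) * 100.0,
    )


@dataclass(frozen=True)
class CandidatePair:
    """A screened population pair with its divergence range and category."""

    population_a: str
    population_b: str
    conspecific: bool
    d_min: float  # percent
    d_max: float  # percent
    d_mean: float  # percent
    category: str  # lump_candidate | split_candidate | grey_zone | none

    def __post_init__(self) -> None:
        if not (self.d_min <= self.d_mean + 1e-12 and self.d_mean <= self.d_max + 1e-12):
            raise ValueError("require d_min <= d_mean <= d_max")
        if self.category not in {"lump_candidate", "split_candidate", "grey_zone", "none"}:
            raise ValueError(f"unknown category {self.category!r}")


def _categorize(
    conspecific: bool, d_min: float, d_max: float, lower: float, upper: float
) -> str:
    overlaps = d_max >= lower and d_min <= upper
    if conspecific:
        if d_min > upper:
            return "split_candidate"
        return "grey_zone" if overlaps else "none"
    if d_max < lower:
        return "lump_candidate"
    return "grey_zone" if overlaps else "none"


def screen_candidates(
    matrix: DistanceMatrix,
    popmap: PopulationMap,
    taxonomy: Mapping[frozenset, bool] | Mapping[tuple, bool],
    lower: float = DEFAULT_LOWER_PCT,
    upper: float = DEFAULT_UPPER_PCT,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> list[CandidatePair]:
    """Flag candidate pairs for lumping/splitting against percent thresholds.

    ``taxonomy`` maps population pairs (tuples or frozensets, order-free) to a
    conspecific flag supplied by the user; conspecificity is never inferred.
    Non-conspecific pairs entirely below ``lower`` are lump candidates;
    conspecific pairs entirely above ``upper`` are split candidates; pairs
    whose range touches ``[lower, upper]`` are grey-zone (band boundaries are
    exclusive for lump/split, inclusive for grey).
    """
    if not lower < upper:
        raise ValueError(f"require lower < upper, got {lower} >= {upper}")
    tax = {frozenset(k): v for k, v in taxonomy.items()}
    if pairs is None:
        pops = popmap.populations
        pairs = list(itertools.combinations(pops, 2))
    out = []
    for a, b in pairs:
        key = frozenset((a, b))
        if key not in tax:
            raise KeyError(f"pair ({a!r}, {b!r}) missing from taxonomy table")
        d_min, d_max, d_mean = between_population_summary(matrix, popmap, a, b)
        cat = _categorize(tax[key], d_min, d_max, lower, upper)
        out.append(
            CandidatePair(
                population_a=a,
                population_b=b,
                conspecific=tax[key],
                d_min=d_min,
                d_max=d_max,
                d_mean=d_mean,
                category=cat,
            )
        )
    return out
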