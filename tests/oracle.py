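"""Independent brute-force oracles used by the test suite.

Everything here is computed from per-base boolean masks or exhaustive
enumeration, deliberately ignoring the package's own sweep/index
implementations, so agreement is meaningful.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations

import numpy as np

from crelink.intervals import GenomeDef, GenomicInterval, IntervalSet


def base_mask(ivs, genome: GenomeDef) -> dict[str, np.ndarray]:
    """Per-chromosome boolean coverage mask of an interval collection."""
    masks = {c: np.zeros(L, dtype=bool) for c, L in genome.lengths.items()}
    for iv in ivs:
        masks[iv.chrom][iv.start:iv.end] = True
    return masks


def base_counts(sets, genome: GenomeDef) -> dict[str, np.ndarray]:
    """Per-base number of interval *sets* covering each position."""
    counts = {c: np.zeros(L, dtype=int) for c, L in genome.lengths.items()}
    for s in sets:
        for chrom, m in base_mask(s, genome).items():
            counts[chrom] += m.astype(int)
    return counts


def oracle_report_a(a: IntervalSet, b: IntervalSet,
                    genome: GenomeDef) -> list[GenomicInterval]:
    """Records of `a` sharing >= 1 base with `b` (mask membership)."""
    bm = base_mask(b, genome)
    return [iv for iv in a if bm[iv.chrom][iv.start:iv.end].any()]


def oracle_report_a_minov(a: IntervalSet, b: IntervalSet,
                          min_overlap_bp: int) -> list[GenomicInterval]:
    """Records of `a` overlapping some single `b` record by >= threshold."""
    return [
        iv for iv in a
        if any(iv.overlap_bp(o) >= min_overlap_bp for o in b)
    ]


def oracle_segments(a: IntervalSet, b: IntervalSet) -> list[tuple]:
    """All (chrom, start, end) overlap segments over record pairs."""
    out = []
    for iv in a:
        for o in b:
            if iv.chrom != o.chrom:
                continue
            s, e = max(iv.start, o.start), min(iv.end, o.end)
            if e - s >= 1:
                out.append((iv.chrom, s, e))
    return sorted(out)


def oracle_subtract(a: IntervalSet, b: IntervalSet,
                    genome: GenomeDef) -> list[GenomicInterval]:
    """Records of `a` with zero shared bases with `b`."""
    bm = base_mask(b, genome)
    return [iv for iv in a if not bm[iv.chrom][iv.start:iv.end].any()]


def runs_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean vector as (start, end) half-open."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return [(int(s), int(e)) for s, e in zip(edges[::2], edges[1::2])]


def hypergeom_sf_exact(x: int, universe: int, M: int, K: int) -> Fraction:
    """P(X >= x) for the hypergeometric by exhaustive enumeration.

    Counts, over all C(universe, K) draws of the cluster set, the
    fraction with at least x of the M special items. Exact rational
    arithmetic; only usable for tiny universes.
    """
    items = range(universe)
    total = 0
    hits = 0
    for draw in combinations(items, K):
        total += 1
        if sum(1 for i in draw if i < M) >= x:
            hits += 1
    return Fraction(hits, total)


def bh_adjust(pvals: list[float]) -> list[float]:
    """Textbook Benjamini-Hochberg step-up q-values."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        val = min(prev, pvals[i] * m / rank)
        q[i] = val
        prev = val
    return q


def random_interval_set(rng: np.random.Generator, genome: GenomeDef,
                        n: int, max_len: int = 50) -> IntervalSet:
    """n random intervals (possibly overlapping), uniform chrom/start."""
    chroms = genome.chroms
    out = []
    for _ in range(n):
        c = chroms[int(rng.integers(len(chroms)))]
        L = int(rng.integers(1, max_len + 1))
        s = int(rng.integers(0, genome.lengths[c] - L + 1))
        out.append(GenomicInterval(c, s, s + L))
    return IntervalSet(out, genome=genome)
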