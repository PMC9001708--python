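"""Cross-species mapping of enhancers and randomization-null enrichment.

Regulatory elements called in a source genome are carried over to a
target genome through alignment-derived block mappings (a simplified,
single-block liftover). Mapped elements are overlapped with
target-species activity marks, and the excess of shared-mark elements
over random expectation is quantified by re-placing the mapped intervals
uniformly at random in the target genome: fold change =
observed / mean(null counts), with an add-one empirical p-value.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .intervals import (
    GenomeDef,
    GenomicInterval,
    IntervalSet,
    SignalTrack,
    merge_intervals,
    _interval_track_stats,
)

log = logging.getLogger(__name__)

__all__ = [
    "LiftMapBlock",
    "MappedElement",
    "EnrichmentOutcome",
    "apply_liftmap",
    "count_shared_marks",
    "shuffle_enrichment",
    "conservation_summary",
    "read_liftmap_tsv",
    "write_liftmap_tsv",
]


@dataclass(frozen=True)
class LiftMapBlock:
    """One alignment block: a source interval and its equal-length image."""

    src: GenomicInterval
    tgt: GenomicInterval
    strand: Literal["+", "-"] = "+"

    def __post_init__(self) -> None:
        if len(self.src) != len(self.tgt):
            raise ValueError("source and target block lengths differ")


@dataclass
class MappedElement:
    """A source-genome element with its target-genome image (if any)."""

    source: GenomicInterval
    target: GenomicInterval | None
    shares_target_mark: bool | None = None
    conservation_mean: float = float("nan")
    conservation_median: float = float("nan")

    @property
    def mapped(self) -> bool:
        return self.target is not None


@dataclass
class EnrichmentOutcome:
    """Observed mark-sharing count against a randomization null."""

    observed: int
    null_counts: np.ndarray
    fold_change: float
    empirical_p: float
    n_shuffles: int
    seed: int
    label: str = ""

    def to_json(self, path: str | Path) -> None:
        null = np.asarray(self.null_counts)
        payload = {
            "label": self.label,
            "observed": int(self.observed),
            "fold_change": self.fold_change,
            "empirical_p": self.empirical_p,
            "n_shuffles": int(self.n_shuffles),
            "seed": int(self.seed),
            "null_summary": {
                "mean": float(null.mean()),
                "sd": float(null.std(ddof=1)) if len(null) > 1 else 0.0,
                "min": int(null.min()),
                "max": int(null.max()),
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _validate_blocks(blocks: Sequence[LiftMapBlock]) -> list[LiftMapBlock]:
    ordered = sorted(blocks, key=lambda b: (b.src.chrom, b.src.start, b.src.end))
    for prev, cur in zip(ordered, ordered[1:]):
        if prev.src.chrom == cur.src.chrom and cur.src.start < prev.src.end:
            raise ValueError(
                f"overlapping source blocks at {cur.src.chrom}:{cur.src.start}"
            )
    return ordered


def apply_liftmap(
    elements: IntervalSet,
    blocks: Sequence[LiftMapBlock],
    min_match: float = 0.95,
) -> list[MappedElement]:
    """Map elements to the target genome through alignment blocks.

    An element maps iff at least ``min_match`` of its length lies within
    a single block; the target interval is the affine image of the
    covered part (coordinate-reversed for minus-strand blocks). Elements
    failing the threshold are reported as unmapped.
    """
    if not 0 < min_match <= 1:
        raise ValueError("min_match must be in (0, 1]")
    ordered = _validate_blocks(blocks)
    out: list[MappedElement] = []
    n_mapped = 0
    for iv in elements:
        best: tuple[int, LiftMapBlock] | None = None
        for blk in ordered:
            if blk.src.chrom != iv.chrom:
                continue
            ov = iv.overlap_bp(blk.src)
            if ov > 0 and (best is None or ov > best[0]):
                best = (ov, blk)
        if best is None or best[0] < min_match * len(iv):
            out.append(MappedElement(iv, None))
            continue
        _, blk = best
        s = max(iv.start, blk.src.start)
        e = min(iv.end, blk.src.end)
        if blk.strand == "+":
            ts = blk.tgt.start + (s - blk.src.start)
            te = blk.tgt.start + (e - blk.src.start)
        else:
            ts = blk.tgt.start + (blk.src.end - e)
            te = blk.tgt.start + (blk.src.end - s)
        out.append(
            MappedElement(iv, GenomicInterval(blk.tgt.chrom, ts, te, iv.name))
        )
        n_mapped += 1
    log.info("liftmap: %d/%d elements mapped (%.1f%%)", n_mapped,
             len(elements), 100 * n_mapped / max(len(elements), 1))
    return out


class _MarkIndex:
    """Merged target marks per chromosome for O(log n) overlap queries."""

    def __init__(self, marks: IntervalSet) -> None:
        merged = merge_intervals(marks)
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ivs in merged.by_chrom().items():
            self.by_chrom[chrom] = (
                np.array([iv.start for iv in ivs], dtype=np.int64),
                np.array([iv.end for iv in ivs], dtype=np.int64),
            )

    def overlaps(self, chrom: str, starts: np.ndarray, ends: np.ndarray
                 ) -> np.ndarray:
        """Boolean vector: does [start, end) overlap any mark on chrom?"""
        if chrom not in self.by_chrom:
            return np.zeros(len(starts), dtype=bool)
        ms, me = self.by_chrom[chrom]
        idx = np.searchsorted(ms, ends, side="left")
        hit = idx > 0
        hit[hit] = me[idx[hit] - 1] > starts[hit]
        return hit


def count_shared_marks(
    mapped: Sequence[MappedElement], target_marks: IntervalSet
) -> int:
    """Flag each mapped element that overlaps any target mark (>=1 bp).

    Sets ``shares_target_mark`` in place on mapped elements (unmapped
    elements keep None) and returns the observed shared count.
    """
    index = _MarkIndex(target_marks)
    observed = 0
    for el in mapped:
        if el.target is None:
            continue
        hit = bool(
            index.overlaps(
                el.target.chrom,
                np.array([el.target.start]),
                np.array([el.target.end]),
            )[0]
        )
        el.shares_target_mark = hit
        observed += hit
    return observed


def shuffle_enrichment(
    mapped_targets: IntervalSet,
    target_marks: IntervalSet,
    genome: GenomeDef,
    n_shuffles: int = 100_000,
    seed: int = 0,
    label: str = "",
) -> EnrichmentOutcome:
    """Fold enrichment of mark sharing over a randomization null.

    The observed statistic is the number of mapped target intervals
    overlapping any mark. Each of ``n_shuffles`` null draws re-places
    every interval independently and uniformly in the target genome
    (length preserved, chromosome weighted by placeable length) and
    recounts. Fold change = observed / mean(null); empirical p uses the
    add-one estimator (1 + #{null >= observed}) / (1 + N), so its floor
    is 1/(N+1).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    index = _MarkIndex(target_marks)
    chroms = genome.chroms
    chrom_lens = np.array([genome.lengths[c] for c in chroms], dtype=np.int64)
    lengths = np.array([len(iv) for iv in mapped_targets], dtype=np.int64)

    observed = count_shared_marks(
        [MappedElement(iv, iv) for iv in mapped_targets], target_marks
    )

    null_counts = np.zeros(n_shuffles, dtype=np.int64)
    # vectorized over shuffles, element by element
    for L in np.unique(lengths):
        m = int((lengths == L).sum())
        placeable = np.maximum(chrom_lens - L + 1, 0)
        total = placeable.sum()
        if total <= 0:
            raise ValueError(f"interval of length {L} does not fit in the genome")
        p = placeable / total
        ci = rng.choice(len(chroms), size=(n_shuffles, m), p=p)
        u = rng.random((n_shuffles, m))
        starts = (u * placeable[ci]).astype(np.int64)
        for k, chrom in enumerate(chroms):
            sel = ci == k
            if not sel.any():
                continue
            s = starts[sel]
            hits = index.overlaps(chrom, s, s + int(L))
            flat = np.zeros(sel.shape, dtype=np.int64)
            flat[sel] = hits
            null_counts += flat.sum(axis=1)

    null_mean = float(null_counts.mean())
    if null_mean == 0:
        warnings.warn("null mean is zero; fold change infinite")
        fc = float("inf") if observed > 0 else float("nan")
    else:
        fc = observed / null_mean
    p_emp = (1 + int((null_counts >= observed).sum())) / (1 + n_shuffles)
    return EnrichmentOutcome(
        observed=observed,
        null_counts=null_counts,
        fold_change=fc,
        empirical_p=float(p_emp),
        n_shuffles=n_shuffles,
        seed=seed,
        label=label,
    )


def conservation_summary(
    mapped: Sequence[MappedElement],
    track: SignalTrack,
) -> dict[str, dict[str, float]]:
    """Per-element conservation stats, grouped by mark sharing.

    Each mapped element gets the width-weighted mean and per-base median
    of the conservation track over its target interval (stored on the
    element). Per group ("shared" / "non-shared"), returns the mean of
    per-element means and the median of per-element medians.
    """
    groups: dict[str, list[MappedElement]] = {"shared": [], "non-shared": []}
    for el in mapped:
        if el.target is None:
            continue
        mean, median = _interval_track_stats(el.target, track)
        el.conservation_mean = mean
        el.conservation_median = median
        key = "shared" if el.shares_target_mark else "non-shared"
        groups[key].append(el)
    out: dict[str, dict[str, float]] = {}
    for key, members in groups.items():
        if not members:
            warnings.warn(f"conservation group {key!r} is empty; omitted")
            continue
        means = np.array([el.conservation_mean for el in members])
        medians = np.array([el.conservation_median for el in members])
        out[key] = {
            "mean": float(means.mean()),
            "median": float(np.median(medians)),
            "n": len(members),
        }
    return out


# ----------------------------------------------------------------------
# I/O: simplified chain files


def read_liftmap_tsv(path: str | Path) -> list[LiftMapBlock]:
    """Read blocks: src_chrom, src_start, src_end, tgt_chrom, tgt_start,
    tgt_end, strand."""
    blocks = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("src_chrom\t"):
            continue
        f = line.rstrip("\n").split("\t")
        blocks.append(
            LiftMapBlock(
                GenomicInterval(f[0], int(f[1]), int(f[2])),
                GenomicInterval(f[3], int(f[4]), int(f[5])),
                f[6],
            )
        )
    return _validate_blocks(blocks)


def write_liftmap_tsv(blocks: Sequence[LiftMapBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("src_chrom\tsrc_start\tsrc_end\ttgt_chrom\ttgt_start\t"
                 "tgt_end\tstrand\n")
        for b in blocks:
            fh.write(
                f"{b.src.chrom}\t{b.src.start}\t{b.src.end}\t"
                f"{b.tgt.chrom}\t{b.tgt.start}\t{b.tgt.end}\t{b.strand}\n"
            )
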