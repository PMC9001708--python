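"""Genomic interval algebra on small genomes.

All coordinates are 0-based half-open (BED convention). An interval
``[start, end)`` on chromosome ``chrom`` covers the bases
``start .. end-1``. Every operation is deterministic: outputs are sorted
by (chrom lexicographic, start, end).

The module is self-contained on purpose: interval overlap, subtraction,
coverage counting and random shuffling are the primitives everything
downstream (catalog construction, contact linking, permutation nulls)
is built on, and each of them is checked against a per-base boolean-mask
oracle in the test suite.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np

__all__ = [
    "GenomeDef",
    "GenomicInterval",
    "IntervalSet",
    "SignalTrack",
    "intersect",
    "subtract",
    "coverage_support",
    "shuffle_intervals",
    "summarize_track",
    "window_signal_matrix",
    "merge_intervals",
]


class GenomeMismatchError(ValueError):
    """Two operands live on different genome definitions."""


@dataclass(frozen=True)
class GenomeDef:
    """A coordinate space: chromosome names and lengths in bp."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValueError("genome must contain at least one chromosome")
        for name, ln in self.lengths.items():
            if ln <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {ln}")

    @property
    def chroms(self) -> list[str]:
        return sorted(self.lengths)

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __len__(self) -> int:
        return len(self.lengths)

    @classmethod
    def from_chrom_sizes(cls, path: str | Path) -> "GenomeDef":
        """Read a two-column (chrom, length) chrom.sizes file."""
        lengths: dict[str, int] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            name, ln = line.split("\t")[:2]
            if name in lengths:
                raise ValueError(f"duplicate chromosome {name!r}")
            lengths[name] = int(ln)
        return cls(lengths)

    def to_chrom_sizes(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{c}\t{self.lengths[c]}\n" for c in self.chroms)
        )


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval, optionally named and scored."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class IntervalSet:
    """An ordered collection of intervals on one genome.

    Members are kept sorted by (chrom, start, end); overlapping members
    are allowed unless an operation's contract says otherwise.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        genome: GenomeDef | None = None,
        label: str = "",
    ) -> None:
        self.intervals: list[GenomicInterval] = sorted(intervals)
        self.genome = genome
        self.label = label
        if genome is not None:
            for iv in self.intervals:
                if iv.chrom not in genome:
                    raise ValueError(f"chromosome {iv.chrom!r} not in genome")
                if iv.end > genome.lengths[iv.chrom]:
                    raise ValueError(
                        f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                        f"chromosome length {genome.lengths[iv.chrom]}"
                    )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet({self.label!r}, n={len(self)})"

    def total_bp(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    # --- BED I/O -----------------------------------------------------

    @classmethod
    def from_bed(
        cls, path: str | Path, genome: GenomeDef | None = None, label: str = ""
    ) -> "IntervalSet":
        """Read BED3/BED6 (tab-separated, half-open coordinates)."""
        ivs = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            name = f[3] if len(f) > 3 and f[3] != "." else None
            score = float(f[4]) if len(f) > 4 and f[4] != "." else None
            ivs.append(GenomicInterval(f[0], int(f[1]), int(f[2]), name, score))
        return cls(ivs, genome=genome, label=label or Path(path).stem)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for iv in self.intervals:
                if iv.name is None and iv.score is None:
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
                else:
                    score = "." if iv.score is None else f"{iv.score:g}"
                    fh.write(
                        f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                        f"{iv.name or '.'}\t{score}\t.\n"
                    )


class SignalTrack:
    """Per-bin signal values: non-overlapping (chrom, start, end, value) runs.

    bedGraph semantics; bases not covered by any run have value 0 by
    convention in every consumer.
    """

    def __init__(
        self,
        rows: Iterable[tuple[str, int, int, float]] = (),
        genome: GenomeDef | None = None,
        label: str = "",
    ) -> None:
        self.genome = genome
        self.label = label
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        grouped: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in rows:
            grouped.setdefault(chrom, []).append((start, end, float(value)))
        for chrom, items in grouped.items():
            items.sort()
            starts = np.array([s for s, _, _ in items], dtype=np.int64)
            ends = np.array([e for _, e, _ in items], dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping bins on {chrom}")
            vals = np.array([v for _, _, v in items], dtype=float)
            self._by_chrom[chrom] = (starts, ends, vals)

    def chrom_arrays(
        self, chrom: str
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        empty = np.array([], dtype=np.int64)
        return self._by_chrom.get(
            chrom, (empty, empty, np.array([], dtype=float))
        )

    def __iter__(self):
        for chrom in sorted(self._by_chrom):
            starts, ends, vals = self._by_chrom[chrom]
            for s, e, v in zip(starts, ends, vals):
                yield chrom, int(s), int(e), float(v)

    def __len__(self) -> int:
        return sum(len(s) for s, _, _ in self._by_chrom.values())

    @classmethod
    def from_bedgraph(
        cls, path: str | Path, genome: GenomeDef | None = None, label: str = ""
    ) -> "SignalTrack":
        rows = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track")):
                continue
            c, s, e, v = line.rstrip("\n").split("\t")[:4]
            rows.append((c, int(s), int(e), float(v)))
        return cls(rows, genome=genome, label=label or Path(path).stem)

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, s, e, v in self:
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.12g}\n")


# ----------------------------------------------------------------------
# set operations


def _check_pair(a: IntervalSet, b: IntervalSet) -> None:
    if a.genome is not None and b.genome is not None and a.genome != b.genome:
        raise GenomeMismatchError(
            f"operands on different genomes: {a.label!r} vs {b.label!r}"
        )


def _max_overlap_with(
    iv: GenomicInterval, starts: Sequence[int], ends_sorted_by_start: Sequence[int]
) -> int:
    """Max per-record overlap of iv with a start-sorted interval list."""
    best = 0
    # candidates: every b with b.start < iv.end; prune by scanning back is
    # unnecessary at the scales used here (toy genomes, <=1e4 records).
    hi = bisect.bisect_left(starts, iv.end)
    for j in range(hi):
        ov = min(iv.end, ends_sorted_by_start[j]) - max(iv.start, starts[j])
        if ov > best:
            best = ov
    return best


def intersect(
    a: IntervalSet,
    b: IntervalSet,
    mode: Literal["report-a", "segments"] = "report-a",
    min_overlap_bp: int = 1,
) -> IntervalSet:
    """Overlap two interval sets.

    mode="report-a" returns each record of `a` that overlaps any record
    of `b` by at least ``min_overlap_bp`` bases, unmodified (keeps names
    and scores). mode="segments" returns the overlap segments themselves,
    one per overlapping (a, b) record pair.
    """
    _check_pair(a, b)
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    if mode not in ("report-a", "segments"):
        raise ValueError(f"unknown mode {mode!r}")
    b_by_chrom = b.by_chrom()
    out: list[GenomicInterval] = []
    for iv in a:
        others = b_by_chrom.get(iv.chrom, [])
        if mode == "report-a":
            starts = [o.start for o in others]
            ends = [o.end for o in others]
            if _max_overlap_with(iv, starts, ends) >= min_overlap_bp:
                out.append(iv)
        else:
            for o in others:
                s, e = max(iv.start, o.start), min(iv.end, o.end)
                if e - s >= min_overlap_bp:
                    out.append(
                        GenomicInterval(iv.chrom, s, e, iv.name, iv.score)
                    )
    return IntervalSet(out, genome=a.genome or b.genome, label=a.label)


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Whole-record exclusion: records of `a` with zero overlap with `b`.

    This mirrors ``bedtools intersect -v`` — a single shared base removes
    the entire record; no trimming is performed.
    """
    _check_pair(a, b)
    b_by_chrom = b.by_chrom()
    out = []
    for iv in a:
        others = b_by_chrom.get(iv.chrom, [])
        starts = [o.start for o in others]
        ends = [o.end for o in others]
        if _max_overlap_with(iv, starts, ends) < 1:
            out.append(iv)
    return IntervalSet(out, genome=a.genome or b.genome, label=a.label)


def merge_intervals(a: IntervalSet) -> IntervalSet:
    """Union of a set's records as maximal non-overlapping runs."""
    out: list[GenomicInterval] = []
    for chrom, ivs in sorted(a.by_chrom().items()):
        cur_s, cur_e = None, None
        for iv in ivs:
            if cur_s is None:
                cur_s, cur_e = iv.start, iv.end
            elif iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        if cur_s is not None:
            out.append(GenomicInterval(chrom, cur_s, cur_e))
    return IntervalSet(out, genome=a.genome, label=a.label)


def coverage_support(sets: Sequence[IntervalSet]) -> SignalTrack:
    """How many input sets cover each base, as maximal constant runs.

    A set covering a base through several of its own (overlapping)
    records still contributes 1 at that base; support counts *sets*,
    not records. Runs with support 0 are omitted.
    """
    if not sets:
        raise ValueError("need at least one interval set")
    genome = next((s.genome for s in sets if s.genome is not None), None)
    for s in sets:
        if s.genome is not None and genome is not None and s.genome != genome:
            raise GenomeMismatchError("sets on different genomes")
    # event sweep per chromosome over merged per-set coverage
    chroms = sorted({iv.chrom for s in sets for iv in s})
    rows: list[tuple[str, int, int, float]] = []
    for chrom in chroms:
        events: dict[int, int] = {}
        for s in sets:
            merged = merge_intervals(
                IntervalSet([iv for iv in s if iv.chrom == chrom])
            )
            for iv in merged:
                events[iv.start] = events.get(iv.start, 0) + 1
                events[iv.end] = events.get(iv.end, 0) - 1
        depth = 0
        prev = None
        for pos in sorted(events):
            if prev is not None and depth > 0 and pos > prev:
                rows.append((chrom, prev, pos, depth))
            depth += events[pos]
            prev = pos
    # merge adjacent runs of equal support
    merged_rows: list[tuple[str, int, int, float]] = []
    for row in rows:
        if (
            merged_rows
            and merged_rows[-1][0] == row[0]
            and merged_rows[-1][2] == row[1]
            and merged_rows[-1][3] == row[3]
        ):
            c, s, _, v = merged_rows[-1]
            merged_rows[-1] = (c, s, row[2], v)
        else:
            merged_rows.append(row)
    return SignalTrack(merged_rows, genome=genome, label="support")


def shuffle_intervals(
    a: IntervalSet,
    genome: GenomeDef,
    seed: int | np.random.Generator,
) -> IntervalSet:
    """One random placement of every interval, lengths preserved.

    For an interval of length L the chromosome is chosen with probability
    proportional to its number of placeable start positions
    (chrom_length − L + 1); the start is then uniform over those
    positions. Placements are independent; shuffled intervals may
    overlap one another. Fully reproducible from the seed.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    chroms = genome.chroms
    lens = np.array([genome.lengths[c] for c in chroms], dtype=np.int64)
    out = []
    for iv in a:
        L = len(iv)
        placeable = lens - L + 1
        placeable = np.where(placeable > 0, placeable, 0)
        total = placeable.sum()
        if total <= 0:
            raise ValueError(
                f"interval of length {L} does not fit on any chromosome"
            )
        ci = rng.choice(len(chroms), p=placeable / total)
        start = int(rng.integers(0, placeable[ci]))
        out.append(GenomicInterval(chroms[ci], start, start + L, iv.name, iv.score))
    return IntervalSet(out, genome=genome, label=a.label)


# ----------------------------------------------------------------------
# signal summarization


def _interval_track_stats(
    iv: GenomicInterval, track: SignalTrack
) -> tuple[float, float]:
    """(width-weighted mean, per-base median) of track values over iv.

    Bases of the interval not covered by any bin count as value 0.
    """
    starts, ends, vals = track.chrom_arrays(iv.chrom)
    n = len(iv)
    if len(starts) == 0:
        return 0.0, 0.0
    lo = int(np.searchsorted(ends, iv.start, side="right"))
    hi = int(np.searchsorted(starts, iv.end, side="left"))
    widths: list[int] = []
    values: list[float] = []
    covered = 0
    for j in range(lo, hi):
        w = int(min(iv.end, ends[j]) - max(iv.start, starts[j]))
        if w > 0:
            widths.append(w)
            values.append(float(vals[j]))
            covered += w
    if covered < n:
        widths.append(n - covered)
        values.append(0.0)
    wa = np.array(widths, dtype=float)
    va = np.array(values, dtype=float)
    mean = float(np.dot(wa, va) / n)
    # weighted median over the interval's n per-base values
    order = np.argsort(va, kind="stable")
    sorted_vals = va[order]
    cum = np.cumsum(wa[order])

    def value_at(idx0: int) -> float:
        # value of the idx0-th (0-based) element of the weight-expanded
        # sorted per-base value vector
        return float(sorted_vals[int(np.searchsorted(cum, idx0, side="right"))])

    if n % 2 == 1:
        median = value_at((n - 1) // 2)
    else:
        median = (value_at(n // 2 - 1) + value_at(n // 2)) / 2.0
    return mean, median


def summarize_track(
    intervals: IntervalSet,
    track: SignalTrack,
    stat: Literal["mean", "median"] = "mean",
) -> np.ndarray:
    """Per-interval summary of a signal track.

    ``mean`` is the width-weighted mean over the interval (uncovered
    bases count as 0); ``median`` is the per-base median under the same
    convention. Intervals overlapping no bin yield 0.
    """
    if stat not in ("mean", "median"):
        raise ValueError(f"unknown stat {stat!r}")
    out = np.empty(len(intervals), dtype=float)
    for i, iv in enumerate(intervals):
        mean, median = _interval_track_stats(iv, track)
        out[i] = mean if stat == "mean" else median
    return out


def window_signal_matrix(
    refs: IntervalSet,
    tracks: Sequence[SignalTrack],
    half_window: int = 5000,
    n_bins: int = 100,
) -> np.ndarray:
    """Signal matrix around reference midpoints.

    For each reference interval the window of ``2*half_window`` bp
    centered on its midpoint is split into ``n_bins`` equal bins; each
    bin holds the width-weighted mean track value (0 where the track or
    the genome is absent). Tracks are concatenated in their given order,
    so the matrix is (n_refs, n_tracks * n_bins).
    """
    if len(refs) == 0:
        raise ValueError("refs must be non-empty")
    window = 2 * half_window
    if window % n_bins != 0:
        raise ValueError("window must divide evenly into n_bins")
    bw = window // n_bins
    mat = np.zeros((len(refs), len(tracks) * n_bins), dtype=float)
    for i, iv in enumerate(refs):
        w0 = iv.midpoint - half_window
        for t, track in enumerate(tracks):
            for b in range(n_bins):
                s, e = w0 + b * bw, w0 + (b + 1) * bw
                if e <= 0:
                    continue
                s_clip = max(s, 0)
                probe = GenomicInterval(iv.chrom, s_clip, e)
                mean, _ = _interval_track_stats(probe, track)
                # out-of-genome bases (left edge) count as 0
                mat[i, t * n_bins + b] = mean * (e - s_clip) / bw
    return mat
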