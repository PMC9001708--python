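"""Tissue enhancer catalog construction.

Builds a catalog of putative active enhancers from replicated H3K27ac
peak sets: replicate-reproducible peaks, exclusion of peaks overlapping
transcription start sites, a recurrent-artifact blacklist from unrelated
tissue panels, tissue-specificity classification against developmental
stage peak sets (PsE = adult-tissue-specific, DevE = developmentally
shared), temporal k-means clustering of stage signal profiles, and
genomic-location annotation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score  # noqa: F401  (re-export for tests)

from .intervals import (
    GenomicInterval,
    IntervalSet,
    SignalTrack,
    coverage_support,
    intersect,
    subtract,
)

log = logging.getLogger(__name__)

__all__ = [
    "TssAnnotation",
    "EnhancerRecord",
    "BlacklistRegion",
    "reproducible_peaks",
    "exclude_tss_overlaps",
    "build_blacklist",
    "classify_specificity",
    "cluster_temporal_profiles",
    "annotate_genomic_location",
]

Location = Literal["promoter-proximal", "exonic", "intronic", "intergenic"]


@dataclass
class TssAnnotation:
    """Gene annotation: TSS points, strands, optional spans and exons.

    ``tss`` maps gene id -> list of (chrom, position, strand); several
    TSSs per gene are allowed. ``spans`` and ``exons`` are optional and
    only needed for genomic-location annotation.
    """

    tss: dict[str, list[tuple[str, int, str]]]
    spans: dict[str, GenomicInterval] = field(default_factory=dict)
    exons: dict[str, list[GenomicInterval]] = field(default_factory=dict)

    def tss_points(self) -> IntervalSet:
        """All TSSs as 1-bp intervals named by gene."""
        ivs = [
            GenomicInterval(chrom, pos, pos + 1, name=gene)
            for gene, sites in self.tss.items()
            for chrom, pos, _ in sites
        ]
        return IntervalSet(ivs, label="tss")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TssAnnotation":
        """Read the minimal annotation TSV.

        Columns: gene, chrom, tss, strand[, span_start, span_end,
        exon_starts, exon_ends] with exon columns comma-separated.
        """
        tss: dict[str, list[tuple[str, int, str]]] = {}
        spans: dict[str, GenomicInterval] = {}
        exons: dict[str, list[GenomicInterval]] = {}
        lines = Path(path).read_text().splitlines()
        for line in lines:
            if not line.strip() or line.startswith("gene\t"):
                continue
            f = line.rstrip("\n").split("\t")
            gene, chrom, pos, strand = f[0], f[1], int(f[2]), f[3]
            tss.setdefault(gene, []).append((chrom, pos, strand))
            if len(f) >= 6 and f[4] and f[5]:
                spans[gene] = GenomicInterval(chrom, int(f[4]), int(f[5]), name=gene)
            if len(f) >= 8 and f[6] and f[7]:
                starts = [int(x) for x in f[6].split(",") if x]
                ends = [int(x) for x in f[7].split(",") if x]
                exons[gene] = [
                    GenomicInterval(chrom, s, e, name=gene)
                    for s, e in zip(starts, ends)
                ]
        return cls(tss=tss, spans=spans, exons=exons)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tchrom\ttss\tstrand\tspan_start\tspan_end\t"
                     "exon_starts\texon_ends\n")
            for gene in sorted(self.tss):
                for chrom, pos, strand in self.tss[gene]:
                    span = self.spans.get(gene)
                    exs = self.exons.get(gene, [])
                    fh.write(
                        f"{gene}\t{chrom}\t{pos}\t{strand}\t"
                        f"{span.start if span else ''}\t{span.end if span else ''}\t"
                        f"{','.join(str(e.start) for e in exs)}\t"
                        f"{','.join(str(e.end) for e in exs)}\n"
                    )


@dataclass
class EnhancerRecord:
    """A catalog entry: interval plus specificity class and annotations."""

    interval: GenomicInterval
    specificity: Literal["PsE", "DevE"]
    cluster: str = "none"  # C1..Ck, only for DevE
    location: Location | None = None
    blacklisted: bool = False

    def __post_init__(self) -> None:
        if self.cluster != "none" and self.specificity != "DevE":
            raise ValueError("only DevE enhancers carry a temporal cluster")


@dataclass
class BlacklistRegion:
    """A genomic run recurrently covered by unrelated tissue peak sets."""

    interval: GenomicInterval
    support: int


def reproducible_peaks(rep1: IntervalSet, rep2: IntervalSet) -> IntervalSet:
    """Peaks present in both replicates.

    Returns the replicate-1 records that overlap any replicate-2 record
    by >=1 bp, keeping replicate-1 names and scores.
    """
    if len(rep1) == 0 or len(rep2) == 0:
        warnings.warn("empty replicate peak set; no reproducible peaks")
        return IntervalSet([], genome=rep1.genome or rep2.genome, label=rep1.label)
    return intersect(rep1, rep2, mode="report-a")


def exclude_tss_overlaps(
    peaks: IntervalSet, tss: TssAnnotation, tss_halfwidth: int = 0
) -> IntervalSet:
    """Drop peaks overlapping any TSS point (extended by +-halfwidth)."""
    points = tss.tss_points()
    if tss_halfwidth > 0:
        points = IntervalSet(
            [
                GenomicInterval(
                    iv.chrom, max(0, iv.start - tss_halfwidth),
                    iv.end + tss_halfwidth, iv.name,
                )
                for iv in points
            ],
            label="tss",
        )
    return subtract(peaks, points)


def build_blacklist(
    tissue_sets: Sequence[IntervalSet], min_support: int = 5
) -> list[BlacklistRegion]:
    """Recurrent-artifact regions: bases covered by >= min_support sets.

    Returns maximal runs where the per-base set support reaches the
    threshold, adjacent qualifying runs merged, each annotated with the
    minimum support over the run.
    """
    if min_support > len(tissue_sets):
        raise ValueError(
            f"min_support={min_support} exceeds number of sets ({len(tissue_sets)})"
        )
    support = coverage_support(tissue_sets)
    out: list[BlacklistRegion] = []
    for chrom, s, e, v in support:
        if v < min_support:
            continue
        if (
            out
            and out[-1].interval.chrom == chrom
            and out[-1].interval.end == s
        ):
            prev = out[-1]
            out[-1] = BlacklistRegion(
                GenomicInterval(chrom, prev.interval.start, e),
                min(prev.support, int(v)),
            )
        else:
            out.append(BlacklistRegion(GenomicInterval(chrom, s, e), int(v)))
    return out


def classify_specificity(
    focal: IntervalSet, stage_sets: Sequence[IntervalSet]
) -> list[EnhancerRecord]:
    """Partition focal-tissue enhancers into tissue-specific vs shared.

    A peak overlapping no developmental stage set (>=1 bp rule) is
    tissue-specific (PsE); otherwise it is developmentally shared (DevE).
    The partition is exhaustive and exclusive.
    """
    if not stage_sets:
        raise ValueError("need at least one developmental stage set")
    shared_flags = np.zeros(len(focal), dtype=bool)
    for stage in stage_sets:
        hits = set(
            (iv.chrom, iv.start, iv.end)
            for iv in intersect(focal, stage, mode="report-a")
        )
        for i, iv in enumerate(focal):
            if (iv.chrom, iv.start, iv.end) in hits:
                shared_flags[i] = True
    records = [
        EnhancerRecord(iv, "DevE" if shared else "PsE")
        for iv, shared in zip(focal, shared_flags)
    ]
    n_pse = sum(r.specificity == "PsE" for r in records)
    log.info(
        "specificity: %d PsE, %d DevE of %d", n_pse, len(records) - n_pse,
        len(records),
    )
    return records


def cluster_temporal_profiles(
    matrix: np.ndarray, k: int = 4, seed: int = 0, n_stages: int | None = None
) -> np.ndarray:
    """k-means clustering of per-enhancer temporal signal profiles.

    ``matrix`` is the window signal matrix (rows = enhancers, columns =
    stage tracks concatenated). Rows are log-scaled (log1p) then
    max-normalized before Euclidean k-means with k-means++ init and a
    fixed seed. Cluster labels are renamed C1..Ck ordered by descending
    cluster mean over the earliest stage's columns, so naming is
    reproducible across runs.

    Returns an array of string labels "C1".."Ck", one per row.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if matrix.size == 0:
        raise ValueError("empty signal matrix")
    if matrix.shape[0] < k:
        raise ValueError("fewer rows than clusters")
    X = np.log1p(np.asarray(matrix, dtype=float))
    row_max = X.max(axis=1, keepdims=True)
    row_max[row_max == 0] = 1.0
    X = X / row_max
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    raw = km.fit_predict(X)
    # order clusters by descending mean signal over the earliest stage
    # (first track's columns when the stage count is known, else whole row)
    n_cols = X.shape[1]
    stage_cols = n_cols // n_stages if n_stages else n_cols
    first_stage = slice(0, max(stage_cols, 1))
    means = [
        X[raw == c, first_stage].mean() if np.any(raw == c) else -np.inf
        for c in range(k)
    ]
    order = np.argsort(means)[::-1]
    rename = {int(c): f"C{rank + 1}" for rank, c in enumerate(order)}
    return np.array([rename[int(c)] for c in raw])


def annotate_genomic_location(
    peaks: IntervalSet, annotation: TssAnnotation
) -> list[Location]:
    """Assign each peak midpoint one genomic-location category.

    Priority: promoter-proximal (midpoint within −1000/+100 bp of a TSS,
    strand-aware) > exonic > intronic (inside a gene span but no exon)
    > intergenic. Categories are exhaustive and mutually exclusive.
    """
    # promoter windows
    prom: list[tuple[str, int, int]] = []
    for sites in annotation.tss.values():
        for chrom, pos, strand in sites:
            if strand == "-":
                prom.append((chrom, pos - 100, pos + 1000 + 1))
            else:
                prom.append((chrom, pos - 1000, pos + 100 + 1))
    exon_list = [e for exs in annotation.exons.values() for e in exs]
    span_list = list(annotation.spans.values())

    def midpoint_in(mid: int, chrom: str, ivs: list[GenomicInterval]) -> bool:
        return any(iv.chrom == chrom and iv.start <= mid < iv.end for iv in ivs)

    out: list[Location] = []
    for iv in peaks:
        mid = iv.midpoint
        if any(c == iv.chrom and s <= mid < e for c, s, e in prom):
            out.append("promoter-proximal")
        elif midpoint_in(mid, iv.chrom, exon_list):
            out.append("exonic")
        elif midpoint_in(mid, iv.chrom, span_list):
            out.append("intronic")
        else:
            out.append("intergenic")
    return out
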