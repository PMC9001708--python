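"""Active-promoter calling and contact-based enhancer-gene linking.

Promoter-directed chromatin-conformation assays (HiChIP) yield counts of
contacts between fixed-width genomic bins ("chunks", 5 kb by default).
After filtering for a minimum interaction count and a maximum genomic
distance, a contact links an enhancer to a gene when one chunk overlaps
the enhancer and the other contains the TSS of an active promoter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .catalog import EnhancerRecord, TssAnnotation, reproducible_peaks
from .intervals import GenomicInterval, IntervalSet

log = logging.getLogger(__name__)

__all__ = [
    "ContactRecord",
    "ActivePromoter",
    "EnhancerGeneLink",
    "call_active_promoters",
    "filter_contacts",
    "link_enhancers_to_genes",
    "read_contacts_tsv",
    "write_contacts_tsv",
    "write_links_tsv",
]


@dataclass(frozen=True)
class ContactRecord:
    """A pair of fixed-width genomic chunks with an interaction count.

    Chunks are canonically ordered (a <= b). Only intra-chromosomal
    contacts can link an enhancer to a gene; trans contacts are dropped
    at filtering.
    """

    chrom_a: str
    start_a: int
    chrom_b: str
    start_b: int
    count: int
    bin_width: int = 5000

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("contact count must be positive")
        if (self.chrom_a, self.start_a) > (self.chrom_b, self.start_b):
            raise ValueError("contact chunks must be canonically ordered (a <= b)")

    @property
    def distance(self) -> int | None:
        """Distance between bin starts; None for trans contacts."""
        if self.chrom_a != self.chrom_b:
            return None
        return abs(self.start_b - self.start_a)

    def chunk_a(self) -> GenomicInterval:
        return GenomicInterval(self.chrom_a, self.start_a, self.start_a + self.bin_width)

    def chunk_b(self) -> GenomicInterval:
        return GenomicInterval(self.chrom_b, self.start_b, self.start_b + self.bin_width)


@dataclass
class ActivePromoter:
    """A gene whose TSS lies inside a replicate-reproducible promoter peak."""

    gene: str
    tss: GenomicInterval
    peak: GenomicInterval


@dataclass
class EnhancerGeneLink:
    """An enhancer linked to a gene by one or more filtered contacts."""

    enhancer: str
    gene: str
    count: int
    distance: int
    specificity: str = ""
    cluster: str = "none"


def call_active_promoters(
    h3k4me3_rep1: IntervalSet,
    h3k4me3_rep2: IntervalSet,
    tss: TssAnnotation,
) -> list[ActivePromoter]:
    """Genes whose TSS lies within a reproducible promoter-mark peak."""
    peaks = reproducible_peaks(h3k4me3_rep1, h3k4me3_rep2)
    out: list[ActivePromoter] = []
    seen: set[tuple[str, str, int]] = set()
    for gene, sites in sorted(tss.tss.items()):
        for chrom, pos, _ in sites:
            for pk in peaks:
                if pk.chrom == chrom and pk.start <= pos < pk.end:
                    key = (gene, chrom, pos)
                    if key not in seen:
                        seen.add(key)
                        out.append(
                            ActivePromoter(
                                gene, GenomicInterval(chrom, pos, pos + 1), pk
                            )
                        )
                    break
    log.info("active promoters: %d TSSs, %d genes",
             len(out), len({p.gene for p in out}))
    return out


def filter_contacts(
    contacts: Sequence[ContactRecord],
    min_count: int = 2,
    max_dist: int = 100_000,
) -> list[ContactRecord]:
    """Keep cis contacts with count >= min_count and distance <= max_dist.

    Both thresholds are inclusive. Trans-chromosomal contacts are dropped
    (with a logged count); input order is preserved. Idempotent.
    """
    n_trans = sum(1 for c in contacts if c.distance is None)
    if n_trans:
        log.info("dropping %d trans-chromosomal contacts", n_trans)
    return [
        c
        for c in contacts
        if c.distance is not None
        and c.count >= min_count
        and c.distance <= max_dist
    ]


def link_enhancers_to_genes(
    contacts: Sequence[ContactRecord],
    enhancers: Sequence[EnhancerRecord],
    promoters: Sequence[ActivePromoter],
) -> list[EnhancerGeneLink]:
    """Enhancer-gene links supported by filtered contacts.

    A link (e, g) exists iff some contact has one chunk overlapping
    enhancer e (>=1 bp) and the other chunk containing the TSS of active
    promoter g. Counts are summed over all supporting contacts; the
    reported distance is |enhancer midpoint - TSS|. Contacts whose two
    chunks coincide are skipped (no self-links).
    """
    # index promoter TSSs by their containing chunk
    bw = contacts[0].bin_width if contacts else 5000
    tss_by_chunk: dict[tuple[str, int], list[ActivePromoter]] = {}
    for p in promoters:
        chunk = (p.tss.chrom, (p.tss.start // bw) * bw)
        tss_by_chunk.setdefault(chunk, []).append(p)

    def enhancers_in_chunk(chrom: str, start: int) -> list[EnhancerRecord]:
        end = start + bw
        return [
            r
            for r in enhancers
            if r.interval.chrom == chrom
            and r.interval.start < end
            and r.interval.end > start
        ]

    agg: dict[tuple[str, str], EnhancerGeneLink] = {}
    for c in contacts:
        if c.bin_width != bw:
            raise ValueError("mixed contact bin widths")
        if (c.chrom_a, c.start_a) == (c.chrom_b, c.start_b):
            continue  # same chunk on both ends: no directional link
        pairs = [
            ((c.chrom_a, c.start_a), (c.chrom_b, c.start_b)),
            ((c.chrom_b, c.start_b), (c.chrom_a, c.start_a)),
        ]
        for (ec, es), (pc, ps) in pairs:
            proms = tss_by_chunk.get((pc, ps), [])
            if not proms:
                continue
            for rec in enhancers_in_chunk(ec, es):
                ename = rec.interval.name or (
                    f"{rec.interval.chrom}:{rec.interval.start}-{rec.interval.end}"
                )
                for p in proms:
                    key = (ename, p.gene)
                    dist = abs(rec.interval.midpoint - p.tss.start)
                    if key in agg:
                        agg[key].count += c.count
                    else:
                        agg[key] = EnhancerGeneLink(
                            ename, p.gene, c.count, dist,
                            rec.specificity, rec.cluster,
                        )
    links = sorted(agg.values(), key=lambda l: (l.enhancer, l.gene))
    log.info("links: %d enhancer-gene pairs, %d unique genes",
             len(links), len({l.gene for l in links}))
    return links


# ----------------------------------------------------------------------
# I/O: flattened contact dumps and link tables


def read_contacts_tsv(path: str | Path) -> list[ContactRecord]:
    """Read contacts: chrom_a, start_a, chrom_b, start_b, count, bin_width."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("chrom_a\t"):
            continue
        f = line.rstrip("\n").split("\t")
        out.append(
            ContactRecord(f[0], int(f[1]), f[2], int(f[3]), int(f[4]), int(f[5]))
        )
    return out


def write_contacts_tsv(contacts: Sequence[ContactRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom_a\tstart_a\tchrom_b\tstart_b\tcount\tbin_width\n")
        for c in contacts:
            fh.write(
                f"{c.chrom_a}\t{c.start_a}\t{c.chrom_b}\t{c.start_b}\t"
                f"{c.count}\t{c.bin_width}\n"
            )


def write_links_tsv(links: Sequence[EnhancerGeneLink], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("enhancer\tgene\tcount\tdistance\tspecificity\tcluster\n")
        for l in links:
            fh.write(
                f"{l.enhancer}\t{l.gene}\t{l.count}\t{l.distance}\t"
                f"{l.specificity}\t{l.cluster}\n"
            )
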