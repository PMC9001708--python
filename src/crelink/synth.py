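"""Synthetic pipeline inputs with planted, recoverable ground truth.

Generates every input the analysis consumes — replicated peak sets,
developmental-stage peak sets, multi-tissue panels with shared artifact
regions, stage signal tracks with four temporal archetypes, binned
contact lists wiring planted enhancers to planted target promoters,
expression matrices with elevated linked-gene expression in the focal
tissue, a cross-species lift map whose mapped elements carry
target-species marks at a chosen enrichment factor, and gene-disease /
motif tables with one planted enriched disease — together with a
GroundTruth record describing exactly what was planted.

Every generator is a pure function of the SimulationConfig: the same
seed yields byte-identical files. Defaults plant representative rates
for a differentiated-tissue regulome (48.2% tissue-specific enhancers,
12.49% of elements liftable to the target genome, mark-sharing
enrichment ~3x, top-140 motif overlaps of 98/63/61) at desk scale.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .catalog import TssAnnotation
from .crossspecies import LiftMapBlock, _MarkIndex
from .intervals import GenomeDef, GenomicInterval, IntervalSet
from .linking import ContactRecord

__all__ = ["SimulationConfig", "GroundTruth", "SyntheticDataset", "simulate_all"]


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 0

    # genomes
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000,
                                 "chr3": 5_000_000}
    )
    target_chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"hchr1": 4_000_000, "hchr2": 4_000_000,
                                 "hchr3": 4_000_000}
    )

    # enhancer catalog
    n_enhancers: int = 600
    pse_fraction: float = 0.482
    reproducibility: float = 1.0
    noise_peaks_per_replicate: int = 40
    peak_length_median: float = 600.0
    peak_length_sigma: float = 0.35
    n_tissue_panels: int = 6
    n_artifact_regions: int = 12
    artifact_min_support: int = 5
    n_blacklist_overlapping: int = 3
    panel_private_peaks: int = 25
    n_stages: int = 4
    # temporal archetypes: flat-high, early-high, late-high, flat-low
    archetype_levels: tuple = ((8, 8, 8, 8), (8, 8, 0, 0), (0, 0, 8, 8),
                               (2, 2, 2, 2))
    archetype_presence: tuple = ((1, 1, 1, 1), (1, 1, 0, 0), (0, 0, 1, 1),
                                 (1, 1, 1, 1))
    stage_extra_peaks: int = 30
    signal_bin: int = 100
    signal_window: int = 5000
    signal_noise_sd: float = 0.3
    background_level: float = 1.0

    # genes and promoters
    n_genes: int = 800
    active_gene_fraction: float = 0.7
    promoter_peak_halfwidth: int = 500

    # contacts
    bin_width: int = 5000
    link_fraction: float = 0.5
    contact_count_mean: float = 4.0
    min_link_chunks: int = 2
    max_link_chunks: int = 16
    n_decoy_low_count: int = 30
    n_decoy_far: int = 20
    n_decoy_nonreg: int = 30
    n_decoy_inactive: int = 20

    # expression
    expression_fold: float = 2.0
    expression_gamma_shape: float = 10.0
    expression_mean: float = 5.0
    expression_sample_noise_sd: float = 0.1
    n_focal_samples: int = 3
    n_control_samples: int = 2
    n_timecourse_stages: int = 8
    timecourse_fold: float = 1.6

    # cross-species
    mapped_fraction: float = 0.1249
    mark_enrichment_rho: float = 3.0
    n_background_marks: int = 400
    mark_length: int = 2500
    block_padding: int = 200
    conservation_high: float = 0.5
    conservation_low: float = 0.05
    conservation_noise_sd: float = 0.02

    # disease and motif tables
    gene_universe: int = 2000
    planted_disease_size: int = 40
    planted_disease_linked_fraction: float = 0.5
    n_decoy_diseases: int = 8
    decoy_disease_size: int = 30
    motif_universe: int = 500
    motif_k: int = 140
    motif_overlap_same: int = 98     # focal-tissue pair across species
    motif_overlap_other: tuple = (63, 61)  # pairs involving the unrelated set
    motif_overlap_triple: int = 40
    motif_tail: int = 30

    def validate(self) -> None:
        for name, v in (("pse_fraction", self.pse_fraction),
                        ("reproducibility", self.reproducibility),
                        ("mapped_fraction", self.mapped_fraction),
                        ("link_fraction", self.link_fraction)):
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.planted_disease_size > self.gene_universe:
            raise ValueError("planted disease larger than gene universe")
        max_peak = self.bin_width - 600  # placement margin inside a chunk
        if min(self.chrom_lengths.values()) < 10 * max_peak:
            raise ValueError("chromosomes too short for the peak lengths")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        raw = json.loads(Path(path).read_text())
        for key in ("archetype_levels", "archetype_presence"):
            if key in raw:
                raw[key] = tuple(tuple(x) for x in raw[key])
        if "motif_overlap_other" in raw:
            raw["motif_overlap_other"] = tuple(raw["motif_overlap_other"])
        return cls(**raw)


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks."""

    enhancers: dict[str, dict]           # name -> chrom/start/end/class/cluster
    links: list[tuple[str, str]]         # (enhancer, gene)
    active_genes: list[str]
    linked_genes: list[str]
    artifact_regions: list[tuple[str, int, int]]
    mapped_elements: list[str]
    shared_mark_elements: list[str]
    planted_disease: str
    disease_gene_sets: dict[str, list[str]]
    motif_overlaps: dict[str, int]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"
        )


@dataclass
class SyntheticDataset:
    """In-memory bundle of all generated inputs plus the ground truth."""

    config: SimulationConfig
    genome: GenomeDef
    target_genome: GenomeDef
    h3k27ac_rep1: IntervalSet
    h3k27ac_rep2: IntervalSet
    stage_sets: list[IntervalSet]
    tissue_panels: list[IntervalSet]
    stage_tracks: list  # SignalTrack per stage
    tss: TssAnnotation
    h3k4me3_rep1: IntervalSet
    h3k4me3_rep2: IntervalSet
    contacts: list[ContactRecord]
    expression_values: "object"          # pandas DataFrame
    expression_samples: "object"
    lift_blocks: list[LiftMapBlock]
    target_marks: IntervalSet
    conservation: "object"               # SignalTrack
    disease_table: list
    homology_pairs: list[tuple[str, str]]
    motif_lists: list
    truth: GroundTruth


# ----------------------------------------------------------------------
# helpers


def _rng_for(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stage,))
    )


def _shuffled(rng: np.random.Generator, items: list) -> list:
    """Seeded shuffle of an arbitrary Python list (kept as a list)."""
    return [items[i] for i in rng.permutation(len(items))]


def make_genome(config: SimulationConfig, target: bool = False) -> GenomeDef:
    """GenomeDef from the configured chromosome spec."""
    spec = config.target_chrom_lengths if target else config.chrom_lengths
    return GenomeDef(dict(spec))


def _chunk_grid(genome: GenomeDef, bin_width: int) -> list[tuple[str, int]]:
    grid = []
    for chrom in genome.chroms:
        n = genome.lengths[chrom] // bin_width
        grid.extend((chrom, i * bin_width) for i in range(n))
    return grid


def _peak_in_chunk(rng, chrom: str, chunk_start: int, bin_width: int,
                   median: float, sigma: float, name: str | None = None,
                   margin: int = 300) -> GenomicInterval:
    length = int(np.clip(rng.lognormal(np.log(median), sigma), 150,
                         bin_width - 2 * margin))
    lo = chunk_start + margin
    hi = chunk_start + bin_width - margin - length
    start = int(rng.integers(lo, max(hi, lo + 1)))
    score = float(rng.uniform(5, 50))
    return GenomicInterval(chrom, start, start + length, name, score)


# ----------------------------------------------------------------------
# stage 1: enhancer catalog inputs


def simulate_catalog_inputs(config: SimulationConfig):
    """Replicate peaks, stage sets, tissue panels, annotation, tracks.

    Plants: true enhancers in both replicates (subject to the
    reproducibility rate), noise peaks in exactly one replicate,
    tissue-specific enhancers in no stage set, shared ones in the stage
    sets dictated by their temporal archetype, artifact regions in at
    least ``artifact_min_support`` tissue panels, and no true enhancer
    overlapping a TSS.
    """
    config.validate()
    rng = _rng_for(config, 1)
    genome = make_genome(config)
    bw = config.bin_width
    grid = _chunk_grid(genome, bw)
    if config.n_enhancers + config.n_genes > len(grid) // 2:
        raise ValueError("genome too crowded for the requested features")
    order = rng.permutation(len(grid))
    free = [grid[i] for i in order]

    # enhancers, one per 5-kb chunk so contact linking is unambiguous
    enhancer_chunks = [free.pop() for _ in range(config.n_enhancers)]
    enhancers: list[GenomicInterval] = []
    for i, (chrom, cs) in enumerate(enhancer_chunks):
        enhancers.append(
            _peak_in_chunk(rng, chrom, cs, bw, config.peak_length_median,
                           config.peak_length_sigma, name=f"enh{i:04d}")
        )

    # class assignment
    n_pse = round(config.pse_fraction * config.n_enhancers)
    classes = _shuffled(
        rng, ["PsE"] * n_pse + ["DevE"] * (config.n_enhancers - n_pse))
    n_arch = len(config.archetype_levels)
    arch_iter = 0
    archetypes: list[int] = []
    for cls in classes:
        if cls == "DevE":
            archetypes.append(arch_iter % n_arch)
            arch_iter += 1
        else:
            archetypes.append(-1)

    # planted enhancer-gene links: target genes near their enhancer
    n_link = round(config.link_fraction * config.n_enhancers)
    linked_idx = sorted(rng.choice(config.n_enhancers, n_link, replace=False))
    free_lookup = set(free)
    gene_chunks: list[tuple[str, int]] = []
    links: list[tuple[str, str]] = []
    for j, ei in enumerate(linked_idx):
        chrom, cs = enhancer_chunks[ei]
        placed = False
        offs = rng.permutation(
            np.arange(config.min_link_chunks, config.max_link_chunks + 1)
        )
        for off in offs:
            for sign in (1, -1):
                cand = (chrom, cs + sign * int(off) * bw)
                if cand in free_lookup:
                    free_lookup.discard(cand)
                    gene_chunks.append(cand)
                    links.append((f"enh{ei:04d}", f"gene{j:04d}"))
                    placed = True
                    break
            if placed:
                break
        if not placed:
            raise ValueError("could not place a target gene near an enhancer")
    free = [c for c in free if c in free_lookup]
    for j in range(len(links), config.n_genes):
        gene_chunks.append(free.pop())

    # gene annotation: TSS, strand, span, two exons
    tss: dict[str, list[tuple[str, int, str]]] = {}
    spans: dict[str, GenomicInterval] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    for j, (chrom, cs) in enumerate(gene_chunks):
        gene = f"gene{j:04d}"
        pos = int(rng.integers(cs + 500, cs + bw - 500))
        strand = "+" if rng.random() < 0.5 else "-"
        glen = int(rng.integers(2000, 20000))
        if strand == "+":
            span = GenomicInterval(
                chrom, pos, min(pos + glen, genome.lengths[chrom]), name=gene)
        else:
            span = GenomicInterval(chrom, max(0, pos - glen), pos + 1, name=gene)
        e1 = GenomicInterval(span.chrom, span.start,
                             min(span.start + 300, span.end), name=gene)
        e2_start = max(span.end - 300, e1.end)
        exs = [e1]
        if e2_start < span.end:
            exs.append(GenomicInterval(span.chrom, e2_start, span.end, name=gene))
        tss[gene] = [(chrom, pos, strand)]
        spans[gene] = span
        exons[gene] = exs
    annotation = TssAnnotation(tss=tss, spans=spans, exons=exons)

    # active genes: all linked genes plus random others up to the fraction
    linked_genes = sorted({g for _, g in links})
    n_active = max(round(config.active_gene_fraction * config.n_genes),
                   len(linked_genes))
    others = [f"gene{j:04d}" for j in range(config.n_genes)
              if f"gene{j:04d}" not in set(linked_genes)]
    extra = list(rng.choice(others, n_active - len(linked_genes), replace=False))
    active_genes = sorted(linked_genes + extra)

    # H3K27ac replicates: true enhancers (reproducible or not), promoter
    # peaks at active TSSs (both reps; removed later by the TSS filter),
    # and replicate-private noise peaks
    rep1: list[GenomicInterval] = []
    rep2: list[GenomicInterval] = []
    for iv in enhancers:
        if rng.random() < config.reproducibility:
            rep1.append(iv)
            rep2.append(dataclasses.replace(iv))
        elif rng.random() < 0.5:
            rep1.append(iv)
        else:
            rep2.append(iv)
    hw = config.promoter_peak_halfwidth
    for gene in active_genes:
        chrom, pos, _ = tss[gene][0]
        pk = GenomicInterval(chrom, max(0, pos - hw), pos + hw,
                             name=f"prom_{gene}", score=30.0)
        rep1.append(pk)
        rep2.append(dataclasses.replace(pk))
    for target in (rep1, rep2):
        for _ in range(config.noise_peaks_per_replicate):
            chrom, cs = free.pop()
            target.append(_peak_in_chunk(rng, chrom, cs, bw,
                                         config.peak_length_median,
                                         config.peak_length_sigma))

    # stage sets per archetype presence, plus unrelated stage background
    stage_sets: list[list[GenomicInterval]] = [[] for _ in range(config.n_stages)]
    for iv, cls, arch in zip(enhancers, classes, archetypes):
        if cls != "DevE":
            continue
        for s in range(config.n_stages):
            if config.archetype_presence[arch][s]:
                stage_sets[s].append(dataclasses.replace(iv))
    for s in range(config.n_stages):
        for _ in range(config.stage_extra_peaks):
            chrom, cs = free.pop()
            stage_sets[s].append(_peak_in_chunk(rng, chrom, cs, bw,
                                                config.peak_length_median,
                                                config.peak_length_sigma))

    # tissue panels with shared artifact regions
    artifact_regions: list[GenomicInterval] = []
    overlapping = rng.choice(config.n_enhancers,
                             config.n_blacklist_overlapping, replace=False)
    for r in range(config.n_artifact_regions):
        if r < config.n_blacklist_overlapping:
            base = enhancers[int(overlapping[r])]
            artifact_regions.append(
                GenomicInterval(base.chrom, base.start, base.end,
                                name=f"artifact{r:02d}")
            )
        else:
            chrom, cs = free.pop()
            artifact_regions.append(
                _peak_in_chunk(rng, chrom, cs, bw, config.peak_length_median,
                               config.peak_length_sigma, name=f"artifact{r:02d}")
            )
    panels: list[list[GenomicInterval]] = [[] for _ in range(config.n_tissue_panels)]
    for region in artifact_regions:
        support = int(rng.integers(config.artifact_min_support,
                                   config.n_tissue_panels + 1))
        members = rng.choice(config.n_tissue_panels, support, replace=False)
        for m in members:
            panels[int(m)].append(dataclasses.replace(region))
    for p in range(config.n_tissue_panels):
        for _ in range(config.panel_private_peaks):
            chrom, cs = free.pop()
            panels[p].append(_peak_in_chunk(rng, chrom, cs, bw,
                                            config.peak_length_median,
                                            config.peak_length_sigma))

    # stage signal tracks: background plus archetype-level signal over
    # each enhancer, binned, emitted over +-window around every enhancer
    from .intervals import SignalTrack
    sb, wlen = config.signal_bin, config.signal_window
    tracks = []
    for s in range(config.n_stages):
        rows = []
        for iv, cls, arch in zip(enhancers, classes, archetypes):
            level = (config.archetype_levels[arch][s]
                     if cls == "DevE" else 0.0)
            mid = iv.midpoint
            w0 = max(0, ((mid - wlen) // sb) * sb)
            w1 = min(genome.lengths[iv.chrom], ((mid + wlen) // sb + 1) * sb)
            for bs in range(w0, w1, sb):
                inside = bs < iv.end and bs + sb > iv.start
                val = config.background_level + (level if inside else 0.0)
                val += abs(rng.normal(0, config.signal_noise_sd))
                rows.append((iv.chrom, bs, min(bs + sb, w1), val))
        # windows of nearby enhancers may cover the same bin: keep the
        # maximum (an enhancer's own signal beats a neighbour's flank)
        best: dict[tuple[str, int], tuple[int, float]] = {}
        for chrom, bs, be, val in rows:
            key = (chrom, bs)
            if key not in best or val > best[key][1]:
                best[key] = (be, val)
        dedup = [(c, bs, be, v) for (c, bs), (be, v) in sorted(best.items())]
        tracks.append(SignalTrack(dedup, genome=genome, label=f"stage{s + 1}"))

    truth_enh = {
        iv.name: {
            "chrom": iv.chrom, "start": iv.start, "end": iv.end,
            "class": cls,
            "cluster": f"A{arch + 1}" if arch >= 0 else "none",
        }
        for iv, cls, arch in zip(enhancers, classes, archetypes)
    }
    state = {
        "genome": genome,
        "enhancers": IntervalSet(enhancers, genome=genome, label="true_enhancers"),
        "classes": classes,
        "archetypes": archetypes,
        "rep1": IntervalSet(rep1, genome=genome, label="h3k27ac_rep1"),
        "rep2": IntervalSet(rep2, genome=genome, label="h3k27ac_rep2"),
        "stage_sets": [
            IntervalSet(s_ivs, genome=genome, label=f"stage{s + 1}")
            for s, s_ivs in enumerate(stage_sets)
        ],
        "panels": [
            IntervalSet(p_ivs, genome=genome, label=f"tissue{p + 1}")
            for p, p_ivs in enumerate(panels)
        ],
        "tracks": tracks,
        "annotation": annotation,
        "links": links,
        "active_genes": active_genes,
        "linked_genes": linked_genes,
        "artifact_regions": [(r.chrom, r.start, r.end) for r in artifact_regions],
        "truth_enhancers": truth_enh,
    }
    return state


# ----------------------------------------------------------------------
# stage 2: contacts and expression


def simulate_contacts_and_expression(config: SimulationConfig, state: dict):
    """Contacts wiring planted links, plus the expression matrix.

    Every planted link contributes one contact with count >= 2 at
    distance <= 100 kb; decoys each violate at least one filter or
    connect chunks holding no enhancer / no active TSS. Linked genes'
    expression is multiplied by the planted fold in the focal group
    only.
    """
    import pandas as pd

    rng = _rng_for(config, 2)
    genome: GenomeDef = state["genome"]
    bw = config.bin_width
    annotation: TssAnnotation = state["annotation"]
    enh_by_name = {iv.name: iv for iv in state["enhancers"]}
    active = set(state["active_genes"])

    def chunk_of(chrom: str, pos: int) -> tuple[str, int]:
        return chrom, (pos // bw) * bw

    reg_chunks: set[tuple[str, int]] = set()
    for iv in state["enhancers"]:
        for cs in range((iv.start // bw) * bw, iv.end, bw):
            reg_chunks.add((iv.chrom, cs))
    for sites in annotation.tss.values():
        for chrom, pos, _ in sites:
            reg_chunks.add(chunk_of(chrom, pos))

    def canonical(a: tuple[str, int], b: tuple[str, int], count: int
                  ) -> ContactRecord:
        (ca, sa), (cb, sb) = sorted([a, b])
        return ContactRecord(ca, sa, cb, sb, count, bw)

    contacts: list[ContactRecord] = []
    # H3K4me3 replicates: active genes reproducible, half of the silent
    # genes in one replicate only
    hw = config.promoter_peak_halfwidth
    k4_rep1, k4_rep2 = [], []
    for gene, sites in sorted(annotation.tss.items()):
        chrom, pos, _ = sites[0]
        pk = GenomicInterval(chrom, max(0, pos - hw), pos + hw, name=gene,
                             score=25.0)
        if gene in active:
            k4_rep1.append(pk)
            k4_rep2.append(dataclasses.replace(pk))
        elif rng.random() < 0.5:
            k4_rep1.append(pk)

    # planted link contacts
    for ename, gene in state["links"]:
        iv = enh_by_name[ename]
        chrom, pos, _ = annotation.tss[gene][0]
        count = 2 + int(rng.poisson(max(config.contact_count_mean - 2, 0)))
        contacts.append(
            canonical(chunk_of(iv.chrom, iv.midpoint), chunk_of(chrom, pos),
                      count)
        )

    grid = _chunk_grid(genome, bw)
    nonreg = _shuffled(rng, [c for c in grid if c not in reg_chunks])

    def pop_nonreg() -> tuple[str, int]:
        return nonreg.pop()

    # decoys that fail the count filter
    for _ in range(config.n_decoy_low_count):
        a = pop_nonreg()
        b = (a[0], a[1] + bw * int(rng.integers(1, 10)))
        contacts.append(canonical(a, b, 1))
    # decoys that fail the distance filter (some from enhancer chunks)
    enh_names = sorted(enh_by_name)
    for i in range(config.n_decoy_far):
        if i % 2 == 0:
            iv = enh_by_name[enh_names[int(rng.integers(len(enh_names)))]]
            a = chunk_of(iv.chrom, iv.midpoint)
        else:
            a = pop_nonreg()
        off = bw * int(rng.integers(21, 60))  # > 100 kb
        b = (a[0], a[1] + off)
        if b[1] + bw > genome.lengths[a[0]]:
            b = (a[0], a[1] - off)
        contacts.append(canonical(a, b, 2 + int(rng.poisson(2))))
    # decoys that pass the filters but touch no enhancer / active TSS
    for _ in range(config.n_decoy_nonreg):
        a = pop_nonreg()
        b = (a[0], a[1] + bw * int(rng.integers(1, 20)))
        if b in reg_chunks or b[1] + bw > genome.lengths[a[0]]:
            continue
        contacts.append(canonical(a, b, 2 + int(rng.poisson(2))))
    # decoys touching an enhancer and the TSS of an INACTIVE gene
    inactive = sorted(set(annotation.tss) - active)
    for i in range(min(config.n_decoy_inactive, len(inactive))):
        gene = inactive[int(rng.integers(len(inactive)))]
        chrom, pos, _ = annotation.tss[gene][0]
        same_chrom = [n for n in enh_names if enh_by_name[n].chrom == chrom]
        cands = [
            n for n in same_chrom
            if abs(enh_by_name[n].midpoint - pos) <= 20 * bw
            and chunk_of(chrom, enh_by_name[n].midpoint) != chunk_of(chrom, pos)
        ]
        if not cands:
            continue
        iv = enh_by_name[cands[int(rng.integers(len(cands)))]]
        contacts.append(
            canonical(chunk_of(iv.chrom, iv.midpoint), chunk_of(chrom, pos),
                      2 + int(rng.poisson(1)))
        )

    # expression matrix
    genes = [f"gene{j:04d}" for j in range(config.n_genes)]
    linked = set(state["linked_genes"])
    scale = config.expression_mean / config.expression_gamma_shape
    base = rng.gamma(config.expression_gamma_shape, scale, size=config.n_genes)
    samples: dict[str, np.ndarray] = {}
    meta_rows = []

    def noisy(mult: np.ndarray) -> np.ndarray:
        return base * mult * rng.lognormal(
            0, config.expression_sample_noise_sd, size=config.n_genes)

    focal_mult = np.array(
        [config.expression_fold if g in linked else 1.0 for g in genes])
    for i in range(config.n_focal_samples):
        name = f"pancreas_{i + 1}"
        samples[name] = noisy(focal_mult)
        meta_rows.append((name, "pancreas", np.nan))
    ones = np.ones(config.n_genes)
    for i in range(config.n_control_samples):
        name = f"muscle_{i + 1}"
        samples[name] = noisy(ones)
        meta_rows.append((name, "muscle", np.nan))

    # time course: early-archetype-linked genes up early, late up late,
    # flat-high archetypes up throughout
    arch_of_gene: dict[str, int] = {}
    truth_enh = state["truth_enhancers"]
    for ename, gene in state["links"]:
        cluster = truth_enh[ename]["cluster"]
        arch_of_gene[gene] = int(cluster[1]) - 1 if cluster != "none" else -1
    n_tc = config.n_timecourse_stages
    for t in range(n_tc):
        mult = np.ones(config.n_genes)
        for j, g in enumerate(genes):
            arch = arch_of_gene.get(g)
            if arch is None or arch < 0:
                continue
            early = t < n_tc // 2
            presence = config.archetype_presence[arch]
            boost = (
                (presence[0] and early) or (presence[-1] and not early)
            )
            if boost:
                mult[j] = config.timecourse_fold
        name = f"tc_{t + 1:02d}"
        samples[name] = noisy(mult)
        meta_rows.append((name, f"stage{t + 1:02d}", float(t + 1)))

    import pandas as pd  # noqa: F811
    values = pd.DataFrame(samples, index=pd.Index(genes, name="gene"))
    meta = pd.DataFrame(meta_rows, columns=["sample", "group", "stage_order"]
                        ).set_index("sample")

    state.update({
        "h3k4me3_rep1": IntervalSet(k4_rep1, genome=genome, label="h3k4me3_rep1"),
        "h3k4me3_rep2": IntervalSet(k4_rep2, genome=genome, label="h3k4me3_rep2"),
        "contacts": contacts,
        "expression_values": values,
        "expression_samples": meta,
    })
    return state


# ----------------------------------------------------------------------
# stage 3: cross-species


def simulate_crossspecies(config: SimulationConfig, state: dict):
    """Lift map, target marks at the planted enrichment, conservation.

    A ``mapped_fraction`` subset of enhancers falls inside lift blocks.
    Among mapped elements the probability of overlapping a target mark is
    ``mark_enrichment_rho`` times the background rate implied by the
    random mark placement; mark-sharing elements get elevated
    conservation scores.
    """
    from .intervals import SignalTrack

    rng = _rng_for(config, 3)
    target = make_genome(config, target=True)
    enhancers: IntervalSet = state["enhancers"]

    mapped_mask = rng.random(len(enhancers)) < config.mapped_fraction
    pad = config.block_padding
    blocks: list[LiftMapBlock] = []
    occupied: list[tuple[str, int, int]] = []
    tchroms = target.chroms
    tlens = np.array([target.lengths[c] for c in tchroms])
    mapped_names: list[str] = []
    mapped_targets: list[GenomicInterval] = []
    for iv, mapped in zip(enhancers, mapped_mask):
        if not mapped:
            continue
        src = GenomicInterval(iv.chrom, max(0, iv.start - pad), iv.end + pad)
        blen = len(src)
        for _ in range(200):
            ci = int(rng.integers(len(tchroms)))
            ts = int(rng.integers(0, tlens[ci] - blen))
            if all(not (c == tchroms[ci] and ts < e and ts + blen > s)
                   for c, s, e in occupied):
                break
        else:
            raise ValueError("could not place a lift block on the target genome")
        occupied.append((tchroms[ci], ts, ts + blen))
        strand = "+" if rng.random() < 0.5 else "-"
        blocks.append(
            LiftMapBlock(src, GenomicInterval(tchroms[ci], ts, ts + blen), strand)
        )
        off = iv.start - src.start
        if strand == "+":
            timg = GenomicInterval(tchroms[ci], ts + off, ts + off + len(iv),
                                   iv.name)
        else:
            timg = GenomicInterval(
                tchroms[ci], ts + (src.end - iv.end),
                ts + (src.end - iv.start), iv.name)
        mapped_names.append(iv.name)
        mapped_targets.append(timg)

    # background marks
    marks: list[GenomicInterval] = []
    for _ in range(config.n_background_marks):
        ci = int(rng.integers(len(tchroms)))
        s = int(rng.integers(0, tlens[ci] - config.mark_length))
        marks.append(GenomicInterval(tchroms[ci], s, s + config.mark_length))
    index = _MarkIndex(IntervalSet(marks))

    def null_prob(length: int) -> float:
        """Exact probability that a random placement overlaps the marks."""
        num = 0
        den = 0
        for chrom in tchroms:
            L = target.lengths[chrom]
            placeable = L - length + 1
            if placeable <= 0:
                continue
            den += placeable
            ms, me = index.by_chrom.get(
                chrom, (np.array([], dtype=np.int64),) * 2)
            runs: list[tuple[int, int]] = []
            for s, e in zip(ms, me):
                lo, hi = max(0, int(s) - length + 1), min(int(e), placeable)
                if hi > lo:
                    if runs and lo <= runs[-1][1]:
                        runs[-1] = (runs[-1][0], max(runs[-1][1], hi))
                    else:
                        runs.append((lo, hi))
            num += sum(hi - lo for lo, hi in runs)
        return num / den if den else 0.0

    # plant marks so that the shared count equals rho times the exact
    # null expectation under the background marks: sum of per-element
    # random-placement overlap probabilities. Deterministic planting
    # keeps the realized enrichment factor at rho up to rounding, rather
    # than adding a binomial layer on top of the shuffle null.
    rho = config.mark_enrichment_rho
    q_sum = 0.0
    bg_hit: dict[str, bool] = {}
    for timg in mapped_targets:
        q = null_prob(len(timg))
        if rho * q > 1:
            raise ValueError("rho x background rate exceeds 1")
        q_sum += q
        bg_hit[timg.name] = bool(index.overlaps(
            timg.chrom, np.array([timg.start]), np.array([timg.end]))[0])
    target_shared = round(rho * q_sum)
    shared = [name for name, hit in bg_hit.items() if hit]
    non_hitters = [t for t in mapped_targets if not bg_hit[t.name]]
    n_extra = max(target_shared - len(shared), 0)
    planted_marks: list[GenomicInterval] = []
    for i in rng.permutation(len(non_hitters))[:n_extra]:
        timg = non_hitters[int(i)]
        planted_marks.append(GenomicInterval(timg.chrom, timg.start, timg.end))
        shared.append(timg.name)
    all_marks = IntervalSet(marks + planted_marks, genome=target,
                            label="target_marks")

    # conservation: elevated over mark-sharing elements
    sb = config.signal_bin
    shared_set = set(shared)
    rows = []
    for timg in mapped_targets:
        level = (config.conservation_high if timg.name in shared_set
                 else config.conservation_low)
        w0 = max(0, ((timg.start - 1000) // sb) * sb)
        w1 = min(target.lengths[timg.chrom], ((timg.end + 1000) // sb + 1) * sb)
        for bs in range(w0, w1, sb):
            val = float(np.clip(
                level + rng.normal(0, config.conservation_noise_sd), 0, 1))
            rows.append((timg.chrom, bs, min(bs + sb, w1), val))
    best: dict[tuple[str, int], tuple[int, float]] = {}
    for chrom, bs, be, val in rows:
        key = (chrom, bs)
        if key not in best or val > best[key][1]:
            best[key] = (be, val)
    dedup = [(c, bs, be, v) for (c, bs), (be, v) in sorted(best.items())]
    conservation = SignalTrack(dedup, genome=target, label="conservation")

    state.update({
        "target_genome": target,
        "lift_blocks": sorted(blocks, key=lambda b: (b.src.chrom, b.src.start)),
        "target_marks": all_marks,
        "conservation": conservation,
        "mapped_names": sorted(mapped_names),
        "shared_mark_elements": sorted(shared),
    })
    return state


# ----------------------------------------------------------------------
# stage 4: disease and motif tables


def simulate_annotation_tables(config: SimulationConfig, state: dict):
    """Gene-disease table with one planted enriched disease; motif lists.

    The planted disease draws a configured fraction of its genes from the
    linked-gene set (enrichment over the uniform expectation); decoy
    diseases draw uniformly. Extra decoys fall below the score or size
    filters to exercise them. Motif lists share a planted core between
    the two focal-tissue datasets and smaller cores with the unrelated
    one.
    """
    from .enrichment import GeneDiseaseAssociation, MotifRankList

    rng = _rng_for(config, 4)
    universe = [f"gene{j:04d}" for j in range(config.n_genes)]
    universe += [f"zpad{j:04d}" for j in range(config.gene_universe -
                                               config.n_genes)]
    homology = [(f"HS_{g.upper()}", g) for g in universe]
    human_of = {g: h for h, g in homology}
    linked = sorted(state["linked_genes"])
    nonlinked = sorted(set(universe) - set(linked))

    table: list[GeneDiseaseAssociation] = []
    disease_gene_sets: dict[str, list[str]] = {}

    def add_disease(name: str, zf_genes: list[str], low_score: bool = False
                    ) -> None:
        disease_gene_sets[name] = sorted(zf_genes)
        for g in zf_genes:
            score = (float(rng.uniform(0.01, 0.1)) if low_score
                     else float(rng.uniform(0.15, 0.8)))
            table.append(GeneDiseaseAssociation(human_of[g], name, score))

    n_from_linked = round(config.planted_disease_linked_fraction *
                          config.planted_disease_size)
    planted = (
        list(rng.choice(linked, n_from_linked, replace=False))
        + list(rng.choice(nonlinked,
                          config.planted_disease_size - n_from_linked,
                          replace=False))
    )
    add_disease("planted_disease", planted)
    for d in range(config.n_decoy_diseases):
        genes = list(rng.choice(universe, config.decoy_disease_size,
                                replace=False))
        add_disease(f"decoy_disease{d:02d}", genes)
    # filter-exercising decoys: text-mining-only scores / too few genes
    add_disease("lowscore_disease",
                list(rng.choice(universe, 30, replace=False)), low_score=True)
    add_disease("tiny_disease", list(rng.choice(universe, 10, replace=False)))

    # motif rank lists with exact pairwise top-k overlaps
    M = _shuffled(rng, [f"motif{j:03d}" for j in range(config.motif_universe)])
    pool = iter(M)

    def take(n: int) -> list[str]:
        return [next(pool) for _ in range(n)]

    t = config.motif_overlap_triple
    ab_only = config.motif_overlap_same - t
    ac_only = config.motif_overlap_other[0] - t
    bc_only = config.motif_overlap_other[1] - t
    core = take(t)
    ab, ac, bc = take(ab_only), take(ac_only), take(bc_only)
    k = config.motif_k
    a_only = take(k - t - ab_only - ac_only)
    b_only = take(k - t - ab_only - bc_only)
    c_only = take(k - t - ac_only - bc_only)
    lists = []
    for name, members in (
        ("zf_pancreas", core + ab + ac + a_only),
        ("hs_pancreas", core + ab + bc + b_only),
        ("embryo", core + ac + bc + c_only),
    ):
        members = _shuffled(rng, list(members))
        tail = take(config.motif_tail)
        lists.append(MotifRankList(name, members + tail))

    state.update({
        "disease_table": table,
        "disease_gene_sets": disease_gene_sets,
        "homology_pairs": homology,
        "motif_lists": lists,
        "planted_disease": "planted_disease",
    })
    return state


# ----------------------------------------------------------------------
# all together


def simulate_all(config: SimulationConfig) -> SyntheticDataset:
    """Run every generator stage and assemble the dataset bundle."""
    state = simulate_catalog_inputs(config)
    state = simulate_contacts_and_expression(config, state)
    state = simulate_crossspecies(config, state)
    state = simulate_annotation_tables(config, state)
    truth = GroundTruth(
        enhancers=state["truth_enhancers"],
        links=state["links"],
        active_genes=state["active_genes"],
        linked_genes=state["linked_genes"],
        artifact_regions=state["artifact_regions"],
        mapped_elements=state["mapped_names"],
        shared_mark_elements=state["shared_mark_elements"],
        planted_disease=state["planted_disease"],
        disease_gene_sets=state["disease_gene_sets"],
        motif_overlaps={
            "zf_pancreas|hs_pancreas": config.motif_overlap_same,
            "zf_pancreas|embryo": config.motif_overlap_other[0],
            "hs_pancreas|embryo": config.motif_overlap_other[1],
        },
    )
    return SyntheticDataset(
        config=config,
        genome=state["genome"],
        target_genome=state["target_genome"],
        h3k27ac_rep1=state["rep1"],
        h3k27ac_rep2=state["rep2"],
        stage_sets=state["stage_sets"],
        tissue_panels=state["panels"],
        stage_tracks=state["tracks"],
        tss=state["annotation"],
        h3k4me3_rep1=state["h3k4me3_rep1"],
        h3k4me3_rep2=state["h3k4me3_rep2"],
        contacts=state["contacts"],
        expression_values=state["expression_values"],
        expression_samples=state["expression_samples"],
        lift_blocks=state["lift_blocks"],
        target_marks=state["target_marks"],
        conservation=state["conservation"],
        disease_table=state["disease_table"],
        homology_pairs=state["homology_pairs"],
        motif_lists=state["motif_lists"],
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write every input in its on-disk dialect plus the truth sidecar."""
    from .linking import write_contacts_tsv
    from .crossspecies import write_liftmap_tsv

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ds.genome.to_chrom_sizes(out / "genome.chrom.sizes")
    ds.target_genome.to_chrom_sizes(out / "target.chrom.sizes")
    ds.h3k27ac_rep1.to_bed(out / "h3k27ac_rep1.bed")
    ds.h3k27ac_rep2.to_bed(out / "h3k27ac_rep2.bed")
    for s, st in enumerate(ds.stage_sets):
        st.to_bed(out / f"stage{s + 1}_peaks.bed")
    for p, panel in enumerate(ds.tissue_panels):
        panel.to_bed(out / f"tissue{p + 1}_peaks.bed")
    for s, tr in enumerate(ds.stage_tracks):
        tr.to_bedgraph(out / f"stage{s + 1}_signal.bedgraph")
    ds.tss.to_tsv(out / "genes.tsv")
    ds.h3k4me3_rep1.to_bed(out / "h3k4me3_rep1.bed")
    ds.h3k4me3_rep2.to_bed(out / "h3k4me3_rep2.bed")
    write_contacts_tsv(ds.contacts, out / "contacts.tsv")
    ds.expression_values.to_csv(out / "expression.tsv", sep="\t",
                                index_label="gene")
    ds.expression_samples.to_csv(out / "samples.tsv", sep="\t",
                                 index_label="sample")
    write_liftmap_tsv(ds.lift_blocks, out / "liftmap.tsv")
    ds.target_marks.to_bed(out / "target_marks.bed")
    ds.conservation.to_bedgraph(out / "conservation.bedgraph")
    with open(out / "disease_table.tsv", "w") as fh:
        fh.write("gene\tdisease_id\tdisease_name\tscore\n")
        for a in ds.disease_table:
            fh.write(f"{a.gene}\t{a.disease}\t{a.disease}\t{a.score:.6f}\n")
    with open(out / "homology.tsv", "w") as fh:
        fh.write("human_gene\ttarget_gene\n")
        for h, g in ds.homology_pairs:
            fh.write(f"{h}\t{g}\n")
    with open(out / "motif_lists.tsv", "w") as fh:
        fh.write("dataset\trank\tmotif\tp\n")
        for lst in ds.motif_lists:
            for r, m in enumerate(lst.motifs, 1):
                fh.write(f"{lst.dataset}\t{r}\t{m}\t{10 ** -(5 - r * 0.01):.3e}\n")
    ds.config.to_json(out / "config.json")
    ds.truth.to_json(out / "ground_truth.json")
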