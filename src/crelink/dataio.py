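"""Load a full input bundle from a directory of plain-text files.

Reads back exactly the dialects the generator writes (BED peak sets,
bedGraph tracks, chrom.sizes, annotation/contact/expression/homology
TSVs), so the pipeline runs identically from disk or from memory. Ground
truth is loaded only if its sidecar is present.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .catalog import TssAnnotation
from .crossspecies import read_liftmap_tsv
from .enrichment import read_disease_table, read_motif_lists
from .intervals import GenomeDef, IntervalSet, SignalTrack
from .linking import read_contacts_tsv
from .synth import GroundTruth, SimulationConfig, SyntheticDataset

__all__ = ["load_dataset"]


def _sorted_glob(root: Path, pattern: str) -> list[Path]:
    return sorted(root.glob(pattern))


def load_dataset(indir: str | Path) -> SyntheticDataset:
    root = Path(indir)
    genome = GenomeDef.from_chrom_sizes(root / "genome.chrom.sizes")
    target = GenomeDef.from_chrom_sizes(root / "target.chrom.sizes")
    config = (SimulationConfig.from_json(root / "config.json")
              if (root / "config.json").exists() else SimulationConfig())
    truth = None
    if (root / "ground_truth.json").exists():
        raw = json.loads((root / "ground_truth.json").read_text())
        raw["links"] = [tuple(x) for x in raw["links"]]
        raw["artifact_regions"] = [tuple(x) for x in raw["artifact_regions"]]
        truth = GroundTruth(**raw)
    values = pd.read_csv(root / "expression.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(root / "samples.tsv", sep="\t", index_col=0)
    return SyntheticDataset(
        config=config,
        genome=genome,
        target_genome=target,
        h3k27ac_rep1=IntervalSet.from_bed(root / "h3k27ac_rep1.bed", genome),
        h3k27ac_rep2=IntervalSet.from_bed(root / "h3k27ac_rep2.bed", genome),
        stage_sets=[IntervalSet.from_bed(p, genome)
                    for p in _sorted_glob(root, "stage?_peaks.bed")],
        tissue_panels=[IntervalSet.from_bed(p, genome)
                       for p in _sorted_glob(root, "tissue?_peaks.bed")],
        stage_tracks=[SignalTrack.from_bedgraph(p, genome)
                      for p in _sorted_glob(root, "stage?_signal.bedgraph")],
        tss=TssAnnotation.from_tsv(root / "genes.tsv"),
        h3k4me3_rep1=IntervalSet.from_bed(root / "h3k4me3_rep1.bed", genome),
        h3k4me3_rep2=IntervalSet.from_bed(root / "h3k4me3_rep2.bed", genome),
        contacts=read_contacts_tsv(root / "contacts.tsv"),
        expression_values=values,
        expression_samples=samples,
        lift_blocks=read_liftmap_tsv(root / "liftmap.tsv"),
        target_marks=IntervalSet.from_bed(root / "target_marks.bed", target),
        conservation=SignalTrack.from_bedgraph(root / "conservation.bedgraph",
                                               target),
        disease_table=read_disease_table(root / "disease_table.tsv"),
        homology_pairs=[
            tuple(line.split("\t"))
            for line in (root / "homology.tsv").read_text().splitlines()[1:]
            if line.strip()
        ],
        motif_lists=read_motif_lists(root / "motif_lists.tsv"),
        truth=truth,
    )
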