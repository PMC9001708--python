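"""Config-driven orchestration of the full analysis.

Runs, in dependency order: enhancer catalog construction, active-promoter
calling and contact-based linking, expression-ratio statistics,
cross-species mapping with the randomization-null enrichment, and
disease/motif enrichment — then assembles a summary report whose
percentages are recomputable from its counts (rounded half-up to one
decimal, matching how such catalogs are conventionally reported).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np

from . import catalog as cat
from . import crossspecies as xs
from . import enrichment as enr
from . import expression as expr
from . import linking as lnk
from .intervals import GenomicInterval, IntervalSet, window_signal_matrix
from .synth import SyntheticDataset

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "SummaryReport", "run_pipeline", "write_report",
           "percent"]


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100*numerator/denominator rounded half-up to ``decimals`` places."""
    if denominator == 0:
        return 0.0
    q = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


@dataclass
class PipelineConfig:
    """Every stage threshold in one place; defaults are the method's."""

    seed: int = 0
    # catalog
    tss_halfwidth: int = 0
    blacklist_min_support: int = 5
    remove_blacklisted: bool = False   # default: annotate only
    kmeans_k: int = 4
    signal_half_window: int = 5000
    signal_n_bins: int = 100
    # linking
    contact_min_count: int = 2
    contact_max_dist: int = 100_000
    # cross-species
    liftmap_min_match: float = 0.95
    n_shuffles: int = 1000
    # enrichment
    disease_min_score: float = 0.1
    disease_min_genes: int = 15
    enrichment_min_ratio: float = 1.5
    q_threshold: float = 0.05
    motif_top_k: int = 140
    # stage toggles
    run_catalog: bool = True
    run_linking: bool = True
    run_expression: bool = True
    run_crossspecies: bool = True
    run_enrichment: bool = True

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SummaryReport:
    """Headline numbers of a pipeline run, all recomputable from counts."""

    config_hash: str = ""
    sections: dict = field(default_factory=dict)

    def self_check(self) -> None:
        """Every stored percentage must equal percent(num, den)."""
        for name, sec in self.sections.items():
            for key, val in sec.items():
                if key.endswith("_pct"):
                    base = key[:-4]
                    num, den = sec[base + "_n"], sec[base + "_of"]
                    expected = percent(num, den)
                    if val != expected:
                        raise AssertionError(
                            f"{name}.{key}={val} != percent({num},{den})"
                            f"={expected}")


def _pct_entry(section: dict, name: str, n: int, of: int) -> None:
    section[f"{name}_n"] = int(n)
    section[f"{name}_of"] = int(of)
    section[f"{name}_pct"] = percent(n, of)


@dataclass
class PipelineResult:
    report: SummaryReport
    records: list = field(default_factory=list)         # EnhancerRecords
    blacklist: list = field(default_factory=list)
    promoters: list = field(default_factory=list)
    links: list = field(default_factory=list)
    ratio_results: dict = field(default_factory=dict)
    enrichment_outcomes: dict = field(default_factory=dict)
    mapped: list = field(default_factory=list)
    disease_results: list = field(default_factory=list)
    motif_overlap: dict = field(default_factory=dict)


def run_pipeline(data: SyntheticDataset, config: PipelineConfig
                 ) -> PipelineResult:
    """Execute all enabled stages on an input bundle."""
    report = SummaryReport(config_hash=config.hash())
    result = PipelineResult(report=report)
    records: list[cat.EnhancerRecord] = []

    if config.run_catalog:
        try:
            reproducible = cat.reproducible_peaks(data.h3k27ac_rep1,
                                                  data.h3k27ac_rep2)
            peaks = cat.exclude_tss_overlaps(reproducible, data.tss,
                                             config.tss_halfwidth)
            blacklist = cat.build_blacklist(data.tissue_panels,
                                            config.blacklist_min_support)
            bl_set = IntervalSet(
                [b.interval for b in blacklist], genome=peaks.genome)
            from .intervals import intersect
            bl_hits = {
                (iv.chrom, iv.start, iv.end)
                for iv in intersect(peaks, bl_set, mode="report-a")
            }
            if config.remove_blacklisted:
                peaks = IntervalSet(
                    [iv for iv in peaks
                     if (iv.chrom, iv.start, iv.end) not in bl_hits],
                    genome=peaks.genome, label=peaks.label)
            records = cat.classify_specificity(peaks, data.stage_sets)
            for r in records:
                key = (r.interval.chrom, r.interval.start, r.interval.end)
                r.blacklisted = key in bl_hits
            deve = [r for r in records if r.specificity == "DevE"]
            if len(deve) >= config.kmeans_k and data.stage_tracks:
                refs = IntervalSet([r.interval for r in deve],
                                   genome=peaks.genome)
                mat = window_signal_matrix(
                    refs, data.stage_tracks,
                    half_window=config.signal_half_window,
                    n_bins=config.signal_n_bins)
                labels = cat.cluster_temporal_profiles(
                    mat, k=config.kmeans_k, seed=config.seed,
                    n_stages=len(data.stage_tracks))
                for r, lab in zip(deve, labels):
                    r.cluster = str(lab)
            locations = cat.annotate_genomic_location(
                IntervalSet([r.interval for r in records]), data.tss)
            for r, loc in zip(records, locations):
                r.location = loc

            sec: dict = {"total": len(records)}
            _pct_entry(sec, "pse",
                       sum(r.specificity == "PsE" for r in records),
                       len(records))
            _pct_entry(sec, "deve",
                       sum(r.specificity == "DevE" for r in records),
                       len(records))
            _pct_entry(sec, "blacklist_overlap",
                       sum(r.blacklisted for r in records), len(records))
            for loc in ("promoter-proximal", "exonic", "intronic",
                        "intergenic"):
                _pct_entry(sec, loc.replace("-", "_"),
                           sum(r.location == loc for r in records),
                           len(records))
            report.sections["catalog"] = sec
            result.records = records
            result.blacklist = blacklist
        except Exception as e:
            raise RuntimeError(f"stage 'catalog' failed: {e}") from e

    if config.run_linking:
        try:
            promoters = lnk.call_active_promoters(
                data.h3k4me3_rep1, data.h3k4me3_rep2, data.tss)
            filtered = lnk.filter_contacts(
                data.contacts, config.contact_min_count,
                config.contact_max_dist)
            links = lnk.link_enhancers_to_genes(filtered, records, promoters)
            report.sections["linking"] = {
                "active_promoter_genes": len({p.gene for p in promoters}),
                "contacts_in": len(data.contacts),
                "contacts_kept": len(filtered),
                "links": len(links),
                "linked_genes": len({l.gene for l in links}),
            }
            result.promoters = promoters
            result.links = links
        except Exception as e:
            raise RuntimeError(f"stage 'linking' failed: {e}") from e

    if config.run_expression:
        try:
            matrix = expr.ExpressionMatrix(data.expression_values,
                                           data.expression_samples)
            linked_genes = sorted({l.gene for l in result.links})
            ratios = {}
            for group in ("pancreas", "muscle"):
                r = expr.hc_allg_ratio(matrix, linked_genes, group)
                p = expr.compare_gene_set_expression(matrix, linked_genes,
                                                     group)
                ratios[group] = {"ratio": r.ratio, "hc_mean": r.hc_mean,
                                 "allg_mean": r.allg_mean, "n_set": r.n_set,
                                 "n_all": r.n_all, "p_one_sided": p}
            by_class: dict[str, set] = {}
            for l in result.links:
                key = l.specificity if l.cluster == "none" else l.cluster
                by_class.setdefault(key, set()).add(l.gene)
            timecourse = expr.ratio_timecourse(matrix, by_class)
            report.sections["expression"] = {
                "ratios": ratios,
                "timecourse": {
                    str(k): [float(x) for x in row]
                    for k, row in timecourse.iterrows()
                },
                "timecourse_stages": list(timecourse.columns),
            }
            result.ratio_results = ratios
        except Exception as e:
            raise RuntimeError(f"stage 'expression' failed: {e}") from e

    if config.run_crossspecies:
        try:
            elements = IntervalSet(
                [r.interval for r in records], genome=data.genome,
                label="catalog") if records else IntervalSet([])
            mapped = xs.apply_liftmap(elements, data.lift_blocks,
                                      config.liftmap_min_match)
            n_mapped = sum(el.mapped for el in mapped)
            observed = xs.count_shared_marks(mapped, data.target_marks)
            mapped_targets = IntervalSet(
                [el.target for el in mapped if el.target is not None],
                genome=data.target_genome)
            outcome = xs.shuffle_enrichment(
                mapped_targets, data.target_marks, data.target_genome,
                n_shuffles=config.n_shuffles, seed=config.seed,
                label="catalog")
            cons = xs.conservation_summary(mapped, data.conservation)
            sec = {}
            _pct_entry(sec, "mapped", n_mapped, len(elements))
            sec.update({
                "shared_marks": observed,
                "fold_change": outcome.fold_change,
                "empirical_p": outcome.empirical_p,
                "n_shuffles": outcome.n_shuffles,
                "conservation": cons,
            })
            report.sections["crossspecies"] = sec
            result.mapped = mapped
            result.enrichment_outcomes["catalog"] = outcome
        except Exception as e:
            raise RuntimeError(f"stage 'crossspecies' failed: {e}") from e

    if config.run_enrichment:
        try:
            homology = enr.HomologyMap(data.homology_pairs)
            disease_sets = enr.filter_disease_table(
                data.disease_table, homology,
                min_score=config.disease_min_score,
                min_genes=config.disease_min_genes)
            linked_genes = {l.gene for l in result.links}
            universe = len({g for _, g in data.homology_pairs})
            results = [
                enr.disease_enrichment(linked_genes, dgenes, universe,
                                       disease=d, cluster="linked")
                for d, dgenes in sorted(disease_sets.items())
            ]
            enr.adjust_fdr(results, alpha=config.q_threshold,
                           min_ratio=config.enrichment_min_ratio)
            motif = enr.motif_topk_overlap(
                data.motif_lists, k=config.motif_top_k,
                universe_size=None)
            report.sections["enrichment"] = {
                "diseases_tested": len(results),
                "significant": sorted(
                    r.disease for r in results if r.significant),
                "motif_pairs": {
                    "|".join(sorted((a, b))): v["observed"]
                    for (a, b), v in sorted(
                        motif["pairs"].items(),
                        key=lambda kv: sorted(kv[0]))
                },
                "motif_E": {
                    "|".join(sorted((a, b))): v["E"]
                    for (a, b), v in sorted(
                        motif["pairs"].items(),
                        key=lambda kv: sorted(kv[0]))
                },
            }
            result.disease_results = results
            result.motif_overlap = motif
        except Exception as e:
            raise RuntimeError(f"stage 'enrichment' failed: {e}") from e

    report.self_check()
    return result


def write_report(report: SummaryReport, path: str | Path,
                 fmt: str = "json") -> None:
    """Serialize the report; percentages are already one-decimal floats."""
    path = Path(path)
    if fmt == "json":
        payload = {"config_hash": report.config_hash, **report.sections}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                                   default=_json_default) + "\n")
    elif fmt == "text":
        lines = [f"config hash: {report.config_hash}"]
        for name, sec in report.sections.items():
            lines.append(f"\n[{name}]")
            for key, val in sec.items():
                if key.endswith("_pct"):
                    base = key[:-4]
                    lines.append(
                        f"  {base}: {sec[base + '_n']} / {sec[base + '_of']}"
                        f" ({val}%)")
                elif not key.endswith(("_n", "_of")):
                    lines.append(f"  {key}: {val}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
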