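"""Target-gene expression enrichment.

Quantifies whether genes linked to enhancers ("HiChIP-connected", HC)
are more highly expressed than the gene universe (AllG): the HC/AllG
ratio of mean expression per sample group, a one-sided rank-sum test of
the linked set against all genes, and the ratio tracked across an
ordered developmental time course.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "RatioResult",
    "hc_allg_ratio",
    "compare_gene_set_expression",
    "ratio_timecourse",
]


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression with sample metadata.

    ``values``: DataFrame, rows = gene ids (unique), columns = sample
    ids, entries >= 0 in consistent normalized units. ``samples``:
    DataFrame indexed by sample id with at least a ``group`` column and
    optionally ``stage_order`` (integer) for time courses.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)}")

    def group_columns(self, group: str) -> list[str]:
        cols = [
            s for s in self.values.columns
            if self.samples.loc[s, "group"] == group
        ]
        if not cols:
            raise ValueError(f"no samples in group {group!r}")
        return cols

    @property
    def stage_groups(self) -> list[str]:
        """Groups carrying a stage order, in that order."""
        meta = self.samples.dropna(subset=["stage_order"])
        return list(
            meta.sort_values("stage_order")["group"].drop_duplicates()
        )

    @classmethod
    def from_tsv(cls, matrix_path: str | Path, samples_path: str | Path
                 ) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        if "stage_order" not in samples.columns:
            samples["stage_order"] = np.nan
        return cls(values, samples)

    def to_tsv(self, matrix_path: str | Path, samples_path: str | Path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="gene")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample")


@dataclass
class RatioResult:
    """HC/AllG mean-expression ratio for one gene set in one sample group."""

    label: str
    group: str
    hc_mean: float
    allg_mean: float
    ratio: float
    n_set: int
    n_all: int
    defined: bool = True


def _intersect_genes(expr: ExpressionMatrix, gene_set: Iterable[str]) -> list[str]:
    genes = [g for g in set(gene_set) if g in expr.values.index]
    dropped = len(set(gene_set)) - len(genes)
    if dropped:
        log.info("dropped %d set genes absent from the matrix", dropped)
    return sorted(genes)


def hc_allg_ratio(
    expr: ExpressionMatrix,
    gene_set: Iterable[str],
    group: str,
    label: str = "HC",
) -> RatioResult:
    """Ratio of mean expression of a gene set to the all-gene mean.

    Both means are arithmetic means over the full (genes x group
    samples) rectangle. Set genes absent from the matrix are dropped
    with a logged count.
    """
    genes = _intersect_genes(expr, gene_set)
    if not genes:
        raise ValueError("gene set has empty intersection with the matrix")
    cols = expr.group_columns(group)
    hc_mean = float(expr.values.loc[genes, cols].to_numpy().mean())
    allg_mean = float(expr.values[cols].to_numpy().mean())
    if allg_mean == 0:
        warnings.warn("all-gene mean is zero; ratio undefined")
        return RatioResult(label, group, hc_mean, allg_mean, float("nan"),
                           len(genes), expr.values.shape[0], defined=False)
    return RatioResult(label, group, hc_mean, allg_mean, hc_mean / allg_mean,
                       len(genes), expr.values.shape[0])


def compare_gene_set_expression(
    expr: ExpressionMatrix,
    gene_set: Iterable[str],
    group: str,
    min_genes: int = 10,
    against: str = "all",
) -> float:
    """One-sided rank-sum test: is the set expressed above the universe?

    Per-gene means over the group's samples are compared between the set
    and all genes (the universe includes the set, mirroring how the HC
    vs AllG comparison is defined; ``against="complement"`` tests against
    the non-set genes instead). Normal approximation with tie
    correction; alternative "set >= all". Returns a p-value in (0, 1].
    """
    genes = _intersect_genes(expr, gene_set)
    if len(genes) < min_genes:
        raise ValueError(f"need >= {min_genes} set genes, got {len(genes)}")
    cols = expr.group_columns(group)
    per_gene = expr.values[cols].mean(axis=1)
    x = per_gene.loc[genes].to_numpy()
    if against == "complement":
        y = per_gene.drop(index=genes).to_numpy()
    else:
        y = per_gene.to_numpy()
    if np.ptp(np.concatenate([x, y])) == 0:
        warnings.warn("degenerate constant expression; p = 1")
        return 1.0
    _, p = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


def ratio_timecourse(
    expr: ExpressionMatrix,
    sets: Mapping[str, Iterable[str]],
    stages: list[str] | None = None,
) -> pd.DataFrame:
    """HC/AllG ratio per gene-set label per ordered stage group.

    Returns a DataFrame with rows = set labels and columns = stages in
    declared order, suitable for plotting.
    """
    stages = stages if stages is not None else expr.stage_groups
    if not sets:
        return pd.DataFrame(columns=stages)
    table = {}
    for label, gene_set in sets.items():
        table[label] = [
            hc_allg_ratio(expr, gene_set, stage, label=label).ratio
            for stage in stages
        ]
    return pd.DataFrame.from_dict(table, orient="index", columns=stages)
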