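"""Disease-gene and motif enrichment statistics.

Disease enrichment: gene-disease association tables (DisGeNET-style,
score in [0, 1]) are filtered for curated-quality associations,
translated into the study species through a homology map, and each
(enhancer-cluster gene set, disease gene set) pair is scored with an
upper-tail hypergeometric test plus the enrichment ratio
(x/K)/(M/universe); Benjamini-Hochberg q-values and a joint
significance rule (ratio >= 1.5 and q <= 0.05) follow.

Motif enrichment: ranked motif lists from independent datasets are cut
at the top k; pairwise overlaps are scored hypergeometrically with the
observed/expected factor E = observed / (k*k/universe).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "GeneDiseaseAssociation",
    "HomologyMap",
    "DiseaseEnrichmentResult",
    "MotifRankList",
    "filter_disease_table",
    "disease_enrichment",
    "adjust_fdr",
    "motif_topk_overlap",
]


@dataclass(frozen=True)
class GeneDiseaseAssociation:
    """One (human gene, disease) association with a curation score."""

    gene: str
    disease: str
    score: float

    def __post_init__(self) -> None:
        if not 0 <= self.score <= 1:
            raise ValueError("association score must be in [0, 1]")


class HomologyMap:
    """Many-to-many mapping between human genes and target-species genes."""

    def __init__(self, pairs: Iterable[tuple[str, str]]) -> None:
        self._fwd: dict[str, set[str]] = {}
        for human, target in pairs:
            self._fwd.setdefault(human, set()).add(target)
        if not self._fwd:
            raise ValueError("empty homology map")

    def translate(self, human_genes: Iterable[str]) -> set[str]:
        """Union of target-species homologs; each counted once."""
        out: set[str] = set()
        for g in human_genes:
            out |= self._fwd.get(g, set())
        return out

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HomologyMap":
        pairs = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("human_gene\t"):
                continue
            f = line.rstrip("\n").split("\t")
            pairs.append((f[0], f[1]))
        return cls(pairs)


@dataclass
class DiseaseEnrichmentResult:
    """Hypergeometric enrichment of a disease gene set in a cluster set.

    X = genes in both the disease and the cluster set; M = disease
    genes; N = universe - M (non-disease genes); K = cluster genes.
    """

    disease: str
    cluster: str
    X: int
    M: int
    N: int
    K: int
    p: float
    ratio: float
    q: float = float("nan")
    significant: bool = False


@dataclass
class MotifRankList:
    """A strictly ranked list of unique motif ids for one dataset."""

    dataset: str
    motifs: list[str]

    def __post_init__(self) -> None:
        if len(set(self.motifs)) != len(self.motifs):
            raise ValueError(f"duplicate motifs in dataset {self.dataset!r}")

    def top(self, k: int) -> set[str]:
        if len(self.motifs) < k:
            raise ValueError(
                f"dataset {self.dataset!r} has {len(self.motifs)} motifs < k={k}"
            )
        return set(self.motifs[:k])


def filter_disease_table(
    table: Sequence[GeneDiseaseAssociation],
    homology: HomologyMap,
    min_score: float = 0.1,
    min_genes: int = 15,
) -> dict[str, set[str]]:
    """Disease -> target-species gene sets after quality filters.

    Associations must have score strictly above ``min_score`` (excluding
    text-mining-only links); human genes are translated through the
    homology map (union of homologs, each target gene counted once); and
    diseases retaining fewer than ``min_genes`` translated genes are
    dropped.
    """
    if not table:
        raise ValueError("empty association table")
    by_disease: dict[str, set[str]] = {}
    for assoc in table:
        if assoc.score > min_score:
            by_disease.setdefault(assoc.disease, set()).add(assoc.gene)
    out = {}
    for disease, humans in sorted(by_disease.items()):
        translated = homology.translate(humans)
        if len(translated) >= min_genes:
            out[disease] = translated
    log.info("disease filter: %d diseases kept of %d scored",
             len(out), len(by_disease))
    return out


def disease_enrichment(
    cluster_genes: set[str],
    disease_genes: set[str],
    universe: int,
    disease: str = "",
    cluster: str = "",
) -> DiseaseEnrichmentResult:
    """Upper-tail hypergeometric enrichment, exact.

    p = P(X >= x) with x = |cluster ∩ disease|, M = |disease|,
    K = |cluster| drawn from a universe of protein-coding genes; the
    ratio is (x/K) / (M/universe).
    """
    if universe < len(cluster_genes | disease_genes):
        raise ValueError("universe smaller than the union of gene sets")
    x = len(cluster_genes & disease_genes)
    M = len(disease_genes)
    K = len(cluster_genes)
    # survival function P(X > x-1) = P(X >= x), exact
    p = float(stats.hypergeom.sf(x - 1, universe, M, K))
    ratio = (x / K) / (M / universe) if K > 0 and M > 0 else 0.0
    return DiseaseEnrichmentResult(
        disease=disease, cluster=cluster, X=x, M=M, N=universe - M, K=K,
        p=min(p, 1.0), ratio=ratio,
    )


def adjust_fdr(
    results: Sequence[DiseaseEnrichmentResult],
    alpha: float = 0.05,
    min_ratio: float = 1.5,
) -> list[DiseaseEnrichmentResult]:
    """Benjamini-Hochberg q-values plus the joint significance rule.

    Significant iff q <= alpha AND enrichment ratio >= min_ratio.
    Results are annotated in place and returned.
    """
    if not results:
        return []
    pvals = np.array([r.p for r in results])
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    for r, q in zip(results, qvals):
        r.q = float(q)
        r.significant = bool(q <= alpha and r.ratio >= min_ratio)
    return list(results)


def motif_topk_overlap(
    lists: Sequence[MotifRankList],
    k: int = 140,
    universe_size: int | None = None,
) -> dict:
    """Overlap structure of the top-k motifs across datasets.

    Returns a dict with:
      - "venn": exclusive overlap counts for every non-empty dataset
        subset (keys are frozensets of dataset names);
      - "pairs": per dataset pair, the observed overlap, the upper-tail
        hypergeometric p of drawing that overlap when both top-k sets
        were random draws from the universe, and E = observed expected
        ratio = observed / (k*k/universe_size).

    ``universe_size`` defaults to the size of the union of the full
    input rank lists.
    """
    if len(lists) < 2:
        raise ValueError("need at least two rank lists")
    if universe_size is None:
        universe_size = len(set().union(*(set(l.motifs) for l in lists)))
    tops = {l.dataset: l.top(k) for l in lists}
    union = set().union(*tops.values())
    if universe_size < len(union):
        raise ValueError("universe smaller than the union of top-k sets")
    if universe_size < k:
        raise ValueError("universe smaller than k")

    names = [l.dataset for l in lists]
    venn: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for subset in itertools.combinations(names, r):
            inside = set.intersection(*(tops[n] for n in subset))
            outside = set().union(
                *(tops[n] for n in names if n not in subset), set()
            )
            venn[frozenset(subset)] = len(inside - outside)

    pairs = {}
    expected = k * k / universe_size
    for a, b in itertools.combinations(names, 2):
        obs = len(tops[a] & tops[b])
        p = float(stats.hypergeom.sf(obs - 1, universe_size, k, k))
        pairs[(a, b)] = {
            "observed": obs,
            "p": min(p, 1.0),
            "E": obs / expected,
        }
    return {"venn": venn, "pairs": pairs, "universe_size": universe_size, "k": k}


# ----------------------------------------------------------------------
# I/O


def read_disease_table(path: str | Path) -> list[GeneDiseaseAssociation]:
    """Read gene, disease_id, disease_name, score (TSV)."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("gene\t"):
            continue
        f = line.rstrip("\n").split("\t")
        out.append(GeneDiseaseAssociation(f[0], f[1], float(f[3])))
    return out


def read_motif_lists(path: str | Path) -> list[MotifRankList]:
    """Read dataset, rank, motif, p (TSV); ranks must be 1..n per dataset."""
    df = pd.read_csv(path, sep="\t")
    lists = []
    for dataset, grp in df.groupby("dataset", sort=True):
        grp = grp.sort_values("rank")
        lists.append(MotifRankList(str(dataset), list(grp["motif"])))
    return lists


def results_to_frame(results: Sequence[DiseaseEnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "disease": r.disease, "cluster": r.cluster, "X": r.X, "M": r.M,
                "N": r.N, "K": r.K, "p": r.p, "q": r.q, "ratio": r.ratio,
                "significant": r.significant,
            }
            for r in results
        ]
    )


def significance_heatmap(results: Sequence[DiseaseEnrichmentResult]
                         ) -> pd.DataFrame:
    """-log10(p) matrix (disease x cluster) for significant cells, else 0."""
    frame = results_to_frame(results)
    if frame.empty:
        return pd.DataFrame()
    frame["neglogp"] = np.where(
        frame["significant"], -np.log10(frame["p"]), 0.0
    )
    return frame.pivot(index="disease", columns="cluster", values="neglogp")
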