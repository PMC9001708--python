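"""Disease enrichment (hypergeometric + BH) and motif top-k overlap."""

import numpy as np
import pytest

from crelink.enrichment import (
    GeneDiseaseAssociation,
    HomologyMap,
    MotifRankList,
    adjust_fdr,
    disease_enrichment,
    filter_disease_table,
    motif_topk_overlap,
)

from oracle import bh_adjust, hypergeom_sf_exact


def test_homology_translation_unions_and_dedupes():
    hm = HomologyMap([("H1", "z1"), ("H1", "z2"), ("H2", "z2"), ("H3", "z3")])
    assert hm.translate(["H1", "H2"]) == {"z1", "z2"}
    assert hm.translate(["HX"]) == set()
    with pytest.raises(ValueError):
        HomologyMap([])


def test_filter_disease_table_score_and_size():
    hm = HomologyMap([(f"H{i}", f"z{i}") for i in range(30)])
    table = (
        # passes: 20 genes, scores above the cutoff
        [GeneDiseaseAssociation(f"H{i}", "good", 0.5) for i in range(20)]
        # dropped: score exactly at the cutoff is NOT above it
        + [GeneDiseaseAssociation(f"H{i}", "atcut", 0.1) for i in range(20)]
        # dropped: too few genes after translation
        + [GeneDiseaseAssociation(f"H{i}", "small", 0.5) for i in range(10)]
    )
    got = filter_disease_table(table, hm, min_score=0.1, min_genes=15)
    assert set(got) == {"good"}
    assert got["good"] == {f"z{i}" for i in range(20)}


def test_disease_enrichment_matches_brute_force():
    # tiny universes: exact enumeration with rational arithmetic
    cases = [
        (10, 4, 3, {0, 1, 2}, {0, 1, 3, 4}),
        (12, 5, 4, {0, 1, 2, 3}, {0, 4, 5, 6, 7}),
        (8, 3, 3, {5, 6, 7}, {5, 6, 7}),
        (9, 2, 4, {0, 1, 2, 3}, {7, 8}),
    ]
    for universe, M, K, cluster, disease in cases:
        cluster_g = {f"g{i}" for i in cluster}
        disease_g = {f"g{i}" for i in disease}
        assert len(cluster_g) == K and len(disease_g) == M
        res = disease_enrichment(cluster_g, disease_g, universe)
        x = len(cluster_g & disease_g)
        exact = hypergeom_sf_exact(x, universe, M, K)
        assert res.X == x
        assert res.p == pytest.approx(float(exact), rel=1e-9)
        if K and M:
            assert res.ratio == pytest.approx((x / K) / (M / universe))


def test_disease_enrichment_universe_guard():
    with pytest.raises(ValueError):
        disease_enrichment({"a", "b"}, {"c", "d"}, universe=3)


def test_adjust_fdr_hand_example():
    # BH on {0.01, 0.02, 0.03, 1.0} -> {0.04, 0.04, 0.04, 1.0}
    results = [
        disease_enrichment(set(), set(), 10, disease=f"d{i}")
        for i in range(4)
    ]
    for r, p in zip(results, [0.01, 0.02, 0.03, 1.0]):
        r.p = p
        r.ratio = 2.0
    adjust_fdr(results, alpha=0.05, min_ratio=1.5)
    assert [r.q for r in results] == pytest.approx([0.04, 0.04, 0.04, 1.0])
    assert [r.significant for r in results] == [True, True, True, False]


def test_adjust_fdr_matches_textbook_bh_random():
    rng = np.random.default_rng(3)
    for _ in range(20):
        ps = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 12)))
        results = [disease_enrichment(set(), set(), 10) for _ in ps]
        for r, p in zip(results, ps):
            r.p = float(p)
        adjust_fdr(results)
        assert [r.q for r in results] == pytest.approx(bh_adjust(list(ps)))


def test_adjust_fdr_joint_rule_requires_ratio():
    results = [disease_enrichment(set(), set(), 10)]
    results[0].p = 0.001
    results[0].ratio = 1.2     # below the 1.5 fold requirement
    adjust_fdr(results)
    assert not results[0].significant


def test_motif_topk_overlap_exact_structure():
    # construct three lists with known exclusive regions
    ids = [f"m{i:03d}" for i in range(300)]
    core, ab, ac, bc = ids[:5], ids[5:15], ids[15:22], ids[22:28]
    a_only, b_only, c_only = ids[30:48], ids[50:69], ids[70:92]
    k = 5 + 10 + 7 + 18          # = |core| + |ab| + |ac| + |a_only| = 40
    a = core + ab + ac + a_only
    b = core + ab + bc + b_only + ids[100:105]   # pad b and c to k
    c = core + ac + bc + c_only + ids[110:112]
    lists = [MotifRankList("A", a + ids[200:210]),
             MotifRankList("B", b + ids[210:220]),
             MotifRankList("C", c + ids[220:230])]
    got = motif_topk_overlap(lists, k=k, universe_size=300)
    venn = got["venn"]
    assert venn[frozenset({"A", "B", "C"})] == 5
    assert venn[frozenset({"A", "B"})] == 10
    assert venn[frozenset({"A", "C"})] == 7
    assert venn[frozenset({"B", "C"})] == 6
    assert venn[frozenset({"A"})] == 18
    pairs = got["pairs"]
    assert pairs[("A", "B")]["observed"] == 15
    assert pairs[("A", "C")]["observed"] == 12
    assert pairs[("B", "C")]["observed"] == 11
    assert pairs[("A", "B")]["E"] == pytest.approx(15 / (k * k / 300))


def test_motif_topk_null_expectation():
    # E statistic: mean observed overlap of two random top-k draws
    # equals k^2/universe, so E averages to 1 under the null
    rng = np.random.default_rng(11)
    universe, k, sims = 200, 30, 800
    ids = np.array([f"m{i}" for i in range(universe)])
    obs = np.empty(sims)
    for s in range(sims):
        a = set(rng.choice(ids, k, replace=False))
        b = set(rng.choice(ids, k, replace=False))
        obs[s] = len(a & b)
    expected = k * k / universe
    se = obs.std(ddof=1) / np.sqrt(sims)
    assert abs(obs.mean() - expected) < 3 * se


def test_motif_topk_validation():
    a = MotifRankList("A", [f"m{i}" for i in range(20)])
    b = MotifRankList("B", [f"m{i}" for i in range(10, 30)])
    with pytest.raises(ValueError):
        motif_topk_overlap([a], k=5)
    with pytest.raises(ValueError):
        motif_topk_overlap([a, b], k=25)    # top() beyond list length
    with pytest.raises(ValueError):
        MotifRankList("dup", ["x", "x"])
    with pytest.raises(ValueError):
        GeneDiseaseAssociation("g", "d", 1.5)
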