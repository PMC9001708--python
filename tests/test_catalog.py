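"""Catalog construction: reproducibility, blacklist, specificity,
clustering, genomic-location annotation."""

import numpy as np
import pytest

from crelink.catalog import (
    TssAnnotation,
    annotate_genomic_location,
    build_blacklist,
    classify_specificity,
    cluster_temporal_profiles,
    exclude_tss_overlaps,
    reproducible_peaks,
)
from crelink.intervals import GenomeDef, GenomicInterval, IntervalSet

GENOME = GenomeDef({"chr1": 100_000})


def iv(chrom, s, e, name=None):
    return GenomicInterval(chrom, s, e, name)


def test_reproducible_peaks_keeps_rep1_records():
    r1 = IntervalSet([iv("chr1", 0, 100, "a"), iv("chr1", 500, 600, "b")])
    r2 = IntervalSet([iv("chr1", 90, 120)])
    got = reproducible_peaks(r1, r2)
    assert [g.name for g in got] == ["a"]
    assert got[0] == iv("chr1", 0, 100)


def test_reproducible_peaks_empty_warns():
    r1 = IntervalSet([iv("chr1", 0, 100)])
    with pytest.warns(UserWarning):
        got = reproducible_peaks(r1, IntervalSet([]))
    assert len(got) == 0


def test_exclude_tss_overlaps_drops_whole_peak():
    tss = TssAnnotation({"g1": [("chr1", 50, "+")]})
    peaks = IntervalSet([iv("chr1", 0, 100, "hit"), iv("chr1", 200, 300, "ok")])
    got = exclude_tss_overlaps(peaks, tss)
    assert [g.name for g in got] == ["ok"]
    # halfwidth extension catches a peak near but not over the TSS point
    peaks2 = IntervalSet([iv("chr1", 55, 100, "near")])
    assert len(exclude_tss_overlaps(peaks2, tss, tss_halfwidth=0)) == 1
    assert len(exclude_tss_overlaps(peaks2, tss, tss_halfwidth=10)) == 0


def test_build_blacklist_support_threshold():
    sets = [IntervalSet([iv("chr1", 0, 100)]) for _ in range(5)]
    sets.append(IntervalSet([iv("chr1", 50, 80)]))
    regions = build_blacklist(sets, min_support=5)
    assert [(r.interval.start, r.interval.end) for r in regions] == [(0, 100)]
    assert regions[0].support == 5          # the minimum support in the run
    regions6 = build_blacklist(sets, min_support=6)
    assert [(r.interval.start, r.interval.end) for r in regions6] == [(50, 80)]
    with pytest.raises(ValueError):
        build_blacklist(sets, min_support=7)


def test_classify_specificity_partition():
    focal = IntervalSet([iv("chr1", 0, 100, "e1"), iv("chr1", 500, 600, "e2")])
    stage = IntervalSet([iv("chr1", 90, 120)])
    recs = classify_specificity(focal, [stage])
    by = {r.interval.start: r.specificity for r in recs}
    assert by == {0: "DevE", 500: "PsE"}
    with pytest.raises(ValueError):
        classify_specificity(focal, [])


def _archetype_matrix(rng, n_per, n_stages=4, cols_per_stage=10):
    """Well-separated synthetic temporal profiles with known classes."""
    rows, labels = [], []
    levels = [(8, 8, 8, 8), (8, 8, 0, 0), (0, 0, 8, 8), (2, 2, 2, 2)]
    for k, lv in enumerate(levels):
        for _ in range(n_per):
            row = np.concatenate([
                np.full(cols_per_stage, 1.0 + lv[s]) +
                rng.normal(0, 0.2, cols_per_stage)
                for s in range(n_stages)
            ])
            rows.append(np.clip(row, 0, None))
            labels.append(k)
    return np.array(rows), np.array(labels)


def test_cluster_temporal_profiles_recovers_archetypes():
    from sklearn.metrics import adjusted_rand_score
    rng = np.random.default_rng(0)
    X, truth = _archetype_matrix(rng, 40)
    labels = cluster_temporal_profiles(X, k=4, seed=0, n_stages=4)
    assert set(labels) == {"C1", "C2", "C3", "C4"}
    assert adjusted_rand_score(truth, labels) > 0.95


def test_cluster_labels_deterministic_and_ordered():
    rng = np.random.default_rng(1)
    X, _ = _archetype_matrix(rng, 20)
    l1 = cluster_temporal_profiles(X, k=4, seed=7, n_stages=4)
    l2 = cluster_temporal_profiles(X, k=4, seed=7, n_stages=4)
    assert (l1 == l2).all()
    # C-labels are ordered by descending normalized early-stage signal,
    # so an early-high row cannot be labeled after a late-high row's label
    means = {}
    Xn = np.log1p(X)
    Xn = Xn / Xn.max(axis=1, keepdims=True)
    for lab in set(l1):
        means[lab] = Xn[l1 == lab, :10].mean()
    ordered = sorted(means, key=lambda k: -means[k])
    assert ordered == sorted(means)   # C1 >= C2 >= ... by construction


def test_cluster_input_validation():
    X = np.ones((3, 8))
    with pytest.raises(ValueError):
        cluster_temporal_profiles(X, k=4)
    with pytest.raises(ValueError):
        cluster_temporal_profiles(np.empty((0, 0)), k=2)
    with pytest.raises(ValueError):
        cluster_temporal_profiles(X, k=1)


def test_annotate_genomic_location_priority():
    ann = TssAnnotation(
        tss={"g+": [("chr1", 10_000, "+")], "g-": [("chr1", 30_000, "-")]},
        spans={"g+": GenomicInterval("chr1", 10_000, 20_000, "g+")},
        exons={"g+": [GenomicInterval("chr1", 10_000, 10_500, "g+"),
                      GenomicInterval("chr1", 15_000, 15_200, "g+")]},
    )
    peaks = IntervalSet([
        iv("chr1", 9_200, 9_300),    # mid 9250: within -1000 of + TSS
        iv("chr1", 10_050, 10_150),  # mid 10100: promoter beats exon
        iv("chr1", 15_000, 15_100),  # mid 15050: exonic
        iv("chr1", 12_000, 12_100),  # mid 12050: intronic (span, no exon)
        iv("chr1", 50_000, 50_100),  # intergenic
        iv("chr1", 30_500, 30_600),  # mid 30550: upstream of - strand TSS
    ])
    got = annotate_genomic_location(peaks, ann)
    # IntervalSet keeps members coordinate-sorted; labels follow that order
    assert got == ["promoter-proximal", "promoter-proximal", "intronic",
                   "exonic", "promoter-proximal", "intergenic"]


def test_promoter_window_is_strand_aware():
    ann = TssAnnotation(tss={"g-": [("chr1", 30_000, "-")]})
    # ~1070 bp downstream (lower coord) of a minus-strand TSS: outside
    got = annotate_genomic_location(
        IntervalSet([iv("chr1", 28_900, 28_960)]), ann)
    assert got == ["intergenic"]
    got2 = annotate_genomic_location(
        IntervalSet([iv("chr1", 29_950, 29_990)]), ann)  # mid 29970, 30 bp down
    assert got2 == ["promoter-proximal"]


def test_tss_annotation_tsv_roundtrip(tmp_path):
    ann = TssAnnotation(
        tss={"g1": [("chr1", 100, "+")], "g2": [("chr1", 900, "-")]},
        spans={"g1": GenomicInterval("chr1", 100, 400, "g1")},
        exons={"g1": [GenomicInterval("chr1", 100, 150, "g1")]},
    )
    p = tmp_path / "genes.tsv"
    ann.to_tsv(p)
    back = TssAnnotation.from_tsv(p)
    assert back.tss == ann.tss
    assert back.spans == ann.spans
    assert back.exons == ann.exons
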