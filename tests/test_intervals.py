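"""Interval-core unit and property tests against per-base oracles."""

import numpy as np
import pytest

from crelink.intervals import (
    GenomeDef,
    GenomicInterval,
    IntervalSet,
    SignalTrack,
    coverage_support,
    intersect,
    merge_intervals,
    shuffle_intervals,
    subtract,
    summarize_track,
    window_signal_matrix,
)

from oracle import (
    base_counts,
    base_mask,
    oracle_report_a,
    oracle_report_a_minov,
    oracle_segments,
    oracle_subtract,
    random_interval_set,
    runs_from_mask,
)

GENOME = GenomeDef({"chr1": 1000, "chr2": 700})


def iv(chrom, s, e, name=None):
    return GenomicInterval(chrom, s, e, name)


# ----------------------------------------------------------------------
# basic types


def test_interval_validation():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 5, 5)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", -1, 5)
    assert len(iv("chr1", 10, 25)) == 15
    assert iv("chr1", 10, 21).midpoint == 15


def test_interval_equality_ignores_name_and_score():
    assert GenomicInterval("chr1", 0, 10, "a", 1.0) == \
        GenomicInterval("chr1", 0, 10, "b", 2.0)


def test_overlap_bp():
    a = iv("chr1", 10, 20)
    assert a.overlap_bp(iv("chr1", 15, 30)) == 5
    assert a.overlap_bp(iv("chr1", 20, 30)) == 0   # half-open: no touch
    assert a.overlap_bp(iv("chr2", 10, 20)) == 0


def test_interval_set_sorted_and_genome_checked():
    s = IntervalSet([iv("chr2", 0, 5), iv("chr1", 50, 60), iv("chr1", 5, 9)],
                    genome=GENOME)
    assert [(x.chrom, x.start) for x in s] == [
        ("chr1", 5), ("chr1", 50), ("chr2", 0)]
    with pytest.raises(ValueError):
        IntervalSet([iv("chrX", 0, 5)], genome=GENOME)
    with pytest.raises(ValueError):
        IntervalSet([iv("chr2", 0, 701)], genome=GENOME)


def test_bed_roundtrip(tmp_path):
    s = IntervalSet([GenomicInterval("chr1", 3, 9, "pk1", 2.5),
                     iv("chr2", 10, 20)], genome=GENOME)
    p = tmp_path / "x.bed"
    s.to_bed(p)
    back = IntervalSet.from_bed(p, GENOME)
    assert back == s
    assert back[0].name == "pk1" and back[0].score == 2.5


def test_signal_track_rejects_overlap_and_roundtrips(tmp_path):
    with pytest.raises(ValueError):
        SignalTrack([("chr1", 0, 10, 1.0), ("chr1", 5, 15, 2.0)])
    t = SignalTrack([("chr1", 0, 10, 1.25), ("chr1", 10, 20, 0.5)],
                    genome=GENOME)
    p = tmp_path / "t.bedgraph"
    t.to_bedgraph(p)
    back = SignalTrack.from_bedgraph(p, GENOME)
    assert list(back) == list(t)


# ----------------------------------------------------------------------
# set operations: hand examples


def test_intersect_report_a_example():
    a = IntervalSet([iv("chr1", 0, 10, "x"), iv("chr1", 20, 30, "y")])
    b = IntervalSet([iv("chr1", 8, 12)])
    got = intersect(a, b, mode="report-a")
    assert [g.name for g in got] == ["x"]
    assert got[0] == iv("chr1", 0, 10)      # unmodified record


def test_intersect_segments_example():
    a = IntervalSet([iv("chr1", 0, 10)])
    b = IntervalSet([iv("chr1", 5, 8), iv("chr1", 9, 20)])
    got = intersect(a, b, mode="segments")
    assert [(g.start, g.end) for g in got] == [(5, 8), (9, 10)]


def test_intersect_min_overlap_threshold():
    a = IntervalSet([iv("chr1", 0, 10)])
    b = IntervalSet([iv("chr1", 7, 20)])
    assert len(intersect(a, b, min_overlap_bp=3)) == 1
    assert len(intersect(a, b, min_overlap_bp=4)) == 0
    with pytest.raises(ValueError):
        intersect(a, b, min_overlap_bp=0)
    with pytest.raises(ValueError):
        intersect(a, b, mode="bogus")


def test_subtract_is_whole_record():
    a = IntervalSet([iv("chr1", 0, 100, "big"), iv("chr1", 200, 210, "far")])
    b = IntervalSet([iv("chr1", 99, 100)])     # one shared base
    got = subtract(a, b)
    assert [g.name for g in got] == ["far"]


def test_merge_adjacent_not_joined():
    a = IntervalSet([iv("chr1", 0, 10), iv("chr1", 10, 20)])
    got = merge_intervals(a)
    # half-open adjacency means no shared base; runs stay separate only
    # if they do not overlap — start == previous end merges them here
    assert [(g.start, g.end) for g in got] == [(0, 20)]
    b = IntervalSet([iv("chr1", 0, 10), iv("chr1", 11, 20)])
    assert [(g.start, g.end) for g in merge_intervals(b)] == [(0, 10), (11, 20)]


def test_coverage_support_counts_sets_not_records():
    # one set covering a base twice still counts once
    s1 = IntervalSet([iv("chr1", 0, 10), iv("chr1", 5, 15)])
    s2 = IntervalSet([iv("chr1", 8, 12)])
    track = coverage_support([s1, s2])
    rows = [(c, s, e, v) for c, s, e, v in track]
    assert rows == [("chr1", 0, 8, 1.0), ("chr1", 8, 12, 2.0),
                    ("chr1", 12, 15, 1.0)]


# ----------------------------------------------------------------------
# property tests against the per-base oracle (>= 200 random cases)


def _random_case(rng):
    n_chroms = int(rng.integers(1, 4))
    genome = GenomeDef({f"c{i}": int(rng.integers(80, 400))
                        for i in range(n_chroms)})
    a = random_interval_set(rng, genome, int(rng.integers(0, 25)))
    b = random_interval_set(rng, genome, int(rng.integers(0, 25)))
    return genome, a, b


def test_oracle_equivalence_random_cases():
    rng = np.random.default_rng(20240917)
    for _ in range(220):
        genome, a, b = _random_case(rng)

        got = intersect(a, b, mode="report-a")
        assert list(got) == oracle_report_a(a, b, genome)

        segs = intersect(a, b, mode="segments")
        assert sorted((g.chrom, g.start, g.end) for g in segs) == \
            oracle_segments(a, b)

        sub = subtract(a, b)
        assert list(sub) == oracle_subtract(a, b, genome)

        # partition: every a-record is reported or subtracted, never both
        assert len(got) + len(sub) == len(a)

        merged = merge_intervals(a)
        mask = base_mask(a, genome)
        for chrom, m in mask.items():
            expect = runs_from_mask(m)
            runs = [(x.start, x.end) for x in merged if x.chrom == chrom]
            assert runs == expect

        # merged segments cover exactly the AND of the two masks
        seg_mask = base_mask(segs, genome)
        bmask = base_mask(b, genome)
        for chrom in genome.chroms:
            assert np.array_equal(seg_mask[chrom], mask[chrom] & bmask[chrom])


def test_oracle_equivalence_min_overlap():
    rng = np.random.default_rng(7)
    for _ in range(60):
        genome, a, b = _random_case(rng)
        t = int(rng.integers(1, 12))
        got = intersect(a, b, mode="report-a", min_overlap_bp=t)
        assert list(got) == oracle_report_a_minov(a, b, t)


def test_coverage_support_random_cases():
    rng = np.random.default_rng(99)
    for _ in range(40):
        n_chroms = int(rng.integers(1, 3))
        genome = GenomeDef({f"c{i}": int(rng.integers(60, 200))
                            for i in range(n_chroms)})
        sets = [random_interval_set(rng, genome, int(rng.integers(0, 10)))
                for _ in range(int(rng.integers(1, 6)))]
        track = coverage_support(sets)
        counts = base_counts(sets, genome)
        recon = {c: np.zeros(L, dtype=int)
                 for c, L in genome.lengths.items()}
        for chrom, s, e, v in track:
            assert float(v).is_integer() and v >= 1
            assert not (recon[chrom][s:e] != 0).any()  # non-overlapping runs
            recon[chrom][s:e] = int(v)
        for chrom in genome.chroms:
            assert np.array_equal(recon[chrom], counts[chrom])


# ----------------------------------------------------------------------
# shuffling


def test_shuffle_preserves_lengths_and_bounds():
    genome = GenomeDef({"c1": 300, "c2": 500})
    rng = np.random.default_rng(5)
    a = random_interval_set(rng, genome, 40, max_len=60)
    sh = shuffle_intervals(a, genome, seed=11)
    assert sorted(len(x) for x in sh) == sorted(len(x) for x in a)
    for x in sh:
        assert 0 <= x.start and x.end <= genome.lengths[x.chrom]


def test_shuffle_reproducible_and_seed_sensitive():
    genome = GenomeDef({"c1": 300, "c2": 500})
    a = random_interval_set(np.random.default_rng(1), genome, 30)
    assert shuffle_intervals(a, genome, 3) == shuffle_intervals(a, genome, 3)
    assert shuffle_intervals(a, genome, 3) != shuffle_intervals(a, genome, 4)


def test_shuffle_chromosome_frequencies_match_closed_form():
    # length-1 intervals: P(c1) = 300 / (300 + 100) = 0.75
    genome = GenomeDef({"c1": 300, "c2": 100})
    a = IntervalSet([iv("c1", 0, 1)] * 1)
    n = 4000
    rng = np.random.default_rng(123)
    hits = sum(shuffle_intervals(a, genome, rng)[0].chrom == "c1"
               for _ in range(n))
    p_hat = hits / n
    se = (0.75 * 0.25 / n) ** 0.5
    assert abs(p_hat - 0.75) < 3 * se


def test_shuffle_rejects_oversized_interval():
    genome = GenomeDef({"c1": 50})
    a = IntervalSet([iv("c1", 0, 50)])
    shuffle_intervals(a, genome, 0)   # exactly fits: one placement
    big = IntervalSet([GenomicInterval("c1", 0, 51)])
    with pytest.raises(ValueError):
        shuffle_intervals(big, GenomeDef({"c1": 50}), 0)


# ----------------------------------------------------------------------
# signal summarization


def test_summarize_track_mean_counts_uncovered_as_zero():
    t = SignalTrack([("chr1", 0, 10, 2.0)])
    s = IntervalSet([iv("chr1", 0, 20)])
    # 10 bases at 2.0, 10 uncovered at 0 -> mean 1.0
    assert summarize_track(s, t, "mean")[0] == pytest.approx(1.0)
    assert summarize_track(IntervalSet([iv("chr1", 50, 60)]), t, "mean")[0] == 0


def test_summarize_track_median_is_per_base():
    t = SignalTrack([("chr1", 0, 6, 5.0), ("chr1", 6, 10, 1.0)])
    s = IntervalSet([iv("chr1", 0, 10)])
    # bases: six 5s, four 1s -> median of 10 values = (5 + 5) / 2? no:
    # sorted [1,1,1,1,5,5,5,5,5,5] -> (5+5)/2 = 5? positions 5,6 are 5,5
    assert summarize_track(s, t, "median")[0] == pytest.approx(5.0)
    t2 = SignalTrack([("chr1", 0, 5, 5.0), ("chr1", 5, 10, 1.0)])
    # sorted [1]*5 + [5]*5 -> median (1+5)/2 = 3
    assert summarize_track(s, t2, "median")[0] == pytest.approx(3.0)


def test_summarize_track_matches_per_base_oracle():
    rng = np.random.default_rng(17)
    genome = GenomeDef({"c1": 200})
    for _ in range(40):
        # random non-overlapping bins
        cuts = np.sort(rng.choice(np.arange(1, 200), size=8, replace=False))
        bounds = [0, *cuts.tolist(), 200]
        rows = []
        for s, e in zip(bounds[:-1], bounds[1:]):
            if rng.random() < 0.7:
                rows.append(("c1", s, e, float(rng.uniform(0, 4))))
        track = SignalTrack(rows, genome=genome)
        ivs = random_interval_set(rng, genome, 10, max_len=80)
        per_base = np.zeros(200)
        for _, s, e, v in track:
            per_base[s:e] = v
        means = summarize_track(ivs, track, "mean")
        medians = summarize_track(ivs, track, "median")
        for j, x in enumerate(ivs):
            seg = per_base[x.start:x.end]
            assert means[j] == pytest.approx(seg.mean())
            assert medians[j] == pytest.approx(np.median(seg))


def test_window_signal_matrix_shape_and_values():
    genome = GenomeDef({"c1": 10_000})
    t = SignalTrack([("c1", 0, 10_000, 3.0)], genome=genome)
    refs = IntervalSet([iv("c1", 4000, 4200)], genome=genome)
    m = window_signal_matrix(refs, [t, t], half_window=1000, n_bins=20)
    assert m.shape == (1, 40)
    assert np.allclose(m, 3.0)
    with pytest.raises(ValueError):
        window_signal_matrix(refs, [t], half_window=1000, n_bins=3)
    with pytest.raises(ValueError):
        window_signal_matrix(IntervalSet([]), [t])


def test_window_signal_matrix_left_edge_zero_padded():
    genome = GenomeDef({"c1": 10_000})
    t = SignalTrack([("c1", 0, 10_000, 2.0)], genome=genome)
    refs = IntervalSet([iv("c1", 0, 2)], genome=genome)   # midpoint 1
    m = window_signal_matrix(refs, [t], half_window=100, n_bins=4)
    # window [-99, 101): first bin [-99, -49) fully out of genome
    assert m[0, 0] == 0.0
    assert m[0, 3] == pytest.approx(2.0)
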