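"""Liftover mapping, mark sharing, shuffle null, conservation summary."""

import numpy as np
import pytest

from crelink.crossspecies import (
    LiftMapBlock,
    MappedElement,
    apply_liftmap,
    conservation_summary,
    count_shared_marks,
    read_liftmap_tsv,
    shuffle_enrichment,
    write_liftmap_tsv,
)
from crelink.intervals import GenomeDef, GenomicInterval, IntervalSet, SignalTrack


def iv(chrom, s, e, name=None):
    return GenomicInterval(chrom, s, e, name)


BLOCKS = [
    LiftMapBlock(iv("chr1", 1_000, 2_000), iv("hchr1", 10_000, 11_000), "+"),
    LiftMapBlock(iv("chr1", 5_000, 6_000), iv("hchr2", 500, 1_500), "-"),
]


def test_liftmap_affine_image_plus_strand():
    els = IntervalSet([iv("chr1", 1_100, 1_300, "e")])
    got = apply_liftmap(els, BLOCKS)
    assert got[0].mapped
    assert got[0].target == iv("hchr1", 10_100, 10_300)


def test_liftmap_minus_strand_reverses():
    els = IntervalSet([iv("chr1", 5_100, 5_300, "e")])
    got = apply_liftmap(els, BLOCKS)
    # offsets from the block end: [6000-5300, 6000-5100) = [700, 900)
    assert got[0].target == iv("hchr2", 500 + 700, 500 + 900)


def test_liftmap_min_match_threshold():
    # 100 of 200 bases inside the block: fails 0.95, passes 0.5
    els = IntervalSet([iv("chr1", 900, 1_100)])
    assert not apply_liftmap(els, BLOCKS, min_match=0.95)[0].mapped
    got = apply_liftmap(els, BLOCKS, min_match=0.5)
    assert got[0].target == iv("hchr1", 10_000, 10_100)
    with pytest.raises(ValueError):
        apply_liftmap(els, BLOCKS, min_match=0.0)


def test_liftmap_block_length_mismatch_rejected():
    with pytest.raises(ValueError):
        LiftMapBlock(iv("chr1", 0, 100), iv("hchr1", 0, 99))


def test_count_shared_marks_flags_in_place():
    marks = IntervalSet([iv("hchr1", 10_200, 10_400)])
    mapped = [
        MappedElement(iv("chr1", 0, 10), iv("hchr1", 10_300, 10_350)),
        MappedElement(iv("chr1", 20, 30), iv("hchr1", 20_000, 20_100)),
        MappedElement(iv("chr1", 40, 50), None),
    ]
    assert count_shared_marks(mapped, marks) == 1
    assert mapped[0].shares_target_mark is True
    assert mapped[1].shares_target_mark is False
    assert mapped[2].shares_target_mark is None


def test_shuffle_enrichment_null_calibration():
    # independent uniform elements and marks: FC near 1, p well-behaved
    genome = GenomeDef({"h1": 1_000_000, "h2": 1_000_000})
    rng = np.random.default_rng(0)
    reps, fcs, ps = 30, [], []
    for r in range(reps):
        marks = IntervalSet([
            (lambda c, s: iv(c, s, s + 2_000))(
                ["h1", "h2"][int(rng.integers(2))],
                int(rng.integers(0, 998_000)))
            for _ in range(60)
        ], genome=genome)
        els = IntervalSet([
            (lambda c, s: iv(c, s, s + 800))(
                ["h1", "h2"][int(rng.integers(2))],
                int(rng.integers(0, 999_200)))
            for _ in range(40)
        ], genome=genome)
        out = shuffle_enrichment(els, marks, genome, n_shuffles=400,
                                 seed=1000 + r)
        fcs.append(out.fold_change)
        ps.append(out.empirical_p)
    fcs, ps = np.array(fcs), np.array(ps)
    assert abs(fcs.mean() - 1.0) < 3 * fcs.std(ddof=1) / np.sqrt(reps)
    se = np.sqrt(0.05 * 0.95 / reps)
    assert (ps <= 0.05).mean() <= 0.05 + 3 * se


def test_shuffle_enrichment_detects_planted_overlap():
    genome = GenomeDef({"h1": 1_000_000})
    marks = IntervalSet([iv("h1", k * 10_000, k * 10_000 + 2_000)
                         for k in range(20)], genome=genome)
    els = IntervalSet([iv("h1", k * 10_000 + 500, k * 10_000 + 1_200)
                       for k in range(20)], genome=genome)
    out = shuffle_enrichment(els, marks, genome, n_shuffles=500, seed=0)
    assert out.observed == 20
    assert out.fold_change > 5
    assert out.empirical_p == pytest.approx(1 / 501)


def test_shuffle_enrichment_reproducible():
    genome = GenomeDef({"h1": 100_000})
    marks = IntervalSet([iv("h1", 0, 10_000)], genome=genome)
    els = IntervalSet([iv("h1", 500, 900), iv("h1", 50_000, 50_300)],
                      genome=genome)
    a = shuffle_enrichment(els, marks, genome, n_shuffles=200, seed=9)
    b = shuffle_enrichment(els, marks, genome, n_shuffles=200, seed=9)
    assert np.array_equal(a.null_counts, b.null_counts)
    assert a.empirical_p == b.empirical_p


def test_empirical_p_floor_is_add_one():
    genome = GenomeDef({"h1": 1_000_000})
    marks = IntervalSet([iv("h1", 0, 1_000)], genome=genome)
    els = IntervalSet([iv("h1", 100, 200)], genome=genome)
    with pytest.warns(UserWarning):  # tiny setup: null mean may be zero
        out = shuffle_enrichment(els, marks, genome, n_shuffles=100, seed=2)
    assert out.empirical_p >= 1 / 101


def test_conservation_summary_groups():
    track = SignalTrack([("h1", 0, 1_000, 0.8), ("h1", 1_000, 2_000, 0.2)])
    mapped = [
        MappedElement(iv("chr1", 0, 10), iv("h1", 0, 100),
                      shares_target_mark=True),
        MappedElement(iv("chr1", 20, 30), iv("h1", 1_500, 1_600),
                      shares_target_mark=False),
        MappedElement(iv("chr1", 40, 50), None),
    ]
    got = conservation_summary(mapped, track)
    assert got["shared"]["mean"] == pytest.approx(0.8)
    assert got["non-shared"]["mean"] == pytest.approx(0.2)
    assert got["shared"]["n"] == 1 and got["non-shared"]["n"] == 1
    with pytest.warns(UserWarning):
        only = conservation_summary([mapped[0]], track)
    assert "non-shared" not in only


def test_liftmap_tsv_roundtrip(tmp_path):
    p = tmp_path / "map.tsv"
    write_liftmap_tsv(BLOCKS, p)
    assert read_liftmap_tsv(p) == BLOCKS
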