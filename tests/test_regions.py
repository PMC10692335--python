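"""Interval consensus, peak densities, read proportions, random regions,
and overlap fractions, each checked against brute-force scans."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import censpa as cs
from censpa.regions import BED_COLUMNS


def _bed(rows):
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def test_consensus_identical_replicates_is_identity():
    rep = _bed([("chr1", 100, 200), ("chr1", 500, 600), ("chr2", 0, 50)])
    out = cs.consensus_peaks([rep, rep.copy(), rep.copy()], min_support=2)
    pd.testing.assert_frame_equal(out.reset_index(drop=True), rep)


def test_singleton_peak_dropped_at_min_support_2():
    r1 = _bed([("chr1", 100, 200), ("chr1", 900, 1000)])
    r2 = _bed([("chr1", 150, 250)])
    r3 = _bed([("chr1", 120, 180)])
    out = cs.consensus_peaks([r1, r2, r3], min_support=2)
    # the 900-1000 singleton is dropped; the overlapping trio merges
    assert len(out) == 1
    assert out.iloc[0]["start"] == 100 and out.iloc[0]["end"] == 250


def _brute_force_support(reps, lo, hi, chrom="chr1"):
    """Per-basepair replicate support counting."""
    cov = np.zeros(hi - lo, dtype=int)
    for rep in reps:
        mask = np.zeros(hi - lo, dtype=bool)
        for c, s, e in rep.itertuples(index=False):
            if c == chrom:
                mask[max(s - lo, 0):max(e - lo, 0)] = True
        cov += mask
    return cov


def test_consensus_matches_per_locus_support_counting():
    rng = np.random.default_rng(7)
    reps = []
    for _ in range(3):
        starts = np.sort(rng.integers(0, 900, size=5))
        reps.append(_bed([("chr1", int(s), int(s) + int(rng.integers(10, 60)))
                          for s in starts]))
    out = cs.consensus_peaks(reps, min_support=2)
    cov = _brute_force_support(reps, 0, 1200)
    union = cs.merge_intervals(pd.concat(reps))
    expect = [
        (c, s, e) for c, s, e in union.itertuples(index=False)
        if cov[s:e].max() >= 2
    ]
    assert list(out.itertuples(index=False, name=None)) == expect


def test_consensus_min_support_extremes():
    r1 = _bed([("chr1", 0, 10)])
    r2 = _bed([("chr1", 5, 15)])
    union = cs.consensus_peaks([r1, r2], min_support=1)
    assert list(union.itertuples(index=False, name=None)) == [("chr1", 0, 15)]
    strict = cs.consensus_peaks([r1, r2], min_support=2)
    assert len(strict) == 1  # merged locus is overlapped by both


def test_density_arithmetic_and_zero_log2():
    region = cs.RegionSet("CenHap", _bed([("chr1", 0, 2_000_000)]))
    peaks = _bed([("chr1", i * 100_000, i * 100_000 + 200) for i in range(5)])
    rec = cs.density_per_region(peaks, [region])[0]
    assert rec.peak_count == 5
    assert rec.density_per_mb == pytest.approx(2.5)
    empty = cs.density_per_region(peaks.iloc[0:0], [region])[0]
    assert empty.peak_count == 0 and np.isnan(empty.log2_density)


def test_density_counts_match_exhaustive_scan():
    rng = np.random.default_rng(11)
    genome = 1_000_000
    peaks = []
    for _ in range(1000):
        s = int(rng.integers(0, genome - 500))
        peaks.append(("chr1", s, s + int(rng.integers(50, 500))))
    peaks = _bed(peaks)
    bounds = [0, 250_000, 500_000, 750_000, genome]
    sets = [
        cs.RegionSet(f"r{i}", _bed([("chr1", bounds[i], bounds[i + 1])]))
        for i in range(4)
    ]
    recs = cs.density_per_region(peaks, sets)
    mids = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    for i, rec in enumerate(recs):
        expect = int(((mids >= bounds[i]) & (mids < bounds[i + 1])).sum())
        assert rec.peak_count == expect
    # labels partition the genome: counts are additive
    assert sum(r.peak_count for r in recs) == len(peaks)


def test_any_overlap_assignment_differs_from_midpoint():
    region = cs.RegionSet("edge", _bed([("chr1", 100, 200)]))
    peaks = _bed([("chr1", 180, 400)])  # midpoint 290 outside, overlap inside
    mid = cs.density_per_region(peaks, [region], assignment="midpoint")[0]
    any_ = cs.density_per_region(peaks, [region], assignment="any-overlap")[0]
    assert mid.peak_count == 0 and any_.peak_count == 1


def test_read_proportions_recover_generating_fractions():
    rng = np.random.default_rng(13)
    genome = 10_000_000
    cen = cs.RegionSet("CenHap", _bed([("chr1", 0, 520_000)]))
    noncen = cs.RegionSet("nonCen", _bed([("chr1", 520_000, genome)]))
    # 5.2% of fragments drawn from the CenHap-like block
    n = 20_000
    frac = 0.052
    rows = []
    for i in range(n):
        if rng.random() < frac:
            s = int(rng.integers(0, 520_000 - 100))
        else:
            s = int(rng.integers(520_000, genome - 100))
        rows.append(("chr1", s, s + 100))
    props = cs.read_proportions(_bed(rows), [cen, noncen])
    se = (frac * (1 - frac) / n) ** 0.5
    assert props["CenHap"] == pytest.approx(frac, abs=4 * se)
    assert props["CenHap"] + props["nonCen"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        cs.read_proportions(_bed([]), [cen])


def test_all_fragments_in_one_region():
    a = cs.RegionSet("A", _bed([("chr1", 0, 1000)]))
    b = cs.RegionSet("B", _bed([("chr2", 0, 1000)]))
    frags = _bed([("chr1", 10, 20), ("chr1", 500, 600)])
    props = cs.read_proportions(frags, [a, b])
    assert props["A"] == 1.0 and props["B"] == 0.0


def test_random_regions_respect_exclusion_and_seed():
    sizes = {"chr1": 1_000_000, "chr2": 400_000}
    excl = cs.RegionSet("cen", _bed([("chr1", 200_000, 600_000)]))
    rs1 = cs.sample_random_regions(sizes, excl, n=100, length_bp=10_000, seed=5)
    rs2 = cs.sample_random_regions(sizes, excl, n=100, length_bp=10_000, seed=5)
    pd.testing.assert_frame_equal(rs1.intervals, rs2.intervals)
    for chrom, s, e in rs1.intervals.itertuples(index=False):
        if chrom == "chr1":
            assert e <= 200_000 or s >= 600_000


def test_random_regions_find_the_only_slot():
    sizes = {"chr1": 1_000}
    excl = cs.RegionSet("x", _bed([("chr1", 0, 400), ("chr1", 500, 1_000)]))
    rs = cs.sample_random_regions(sizes, excl, n=3, length_bp=100, seed=1)
    for _, s, e in rs.intervals.itertuples(index=False):
        assert s >= 400 and e <= 500


def test_random_region_starts_are_uniform():
    """Chi-square GOF on start positions over the allowed space, n=10,000.

    Length-1 regions on a 10 Mb chromosome: merging collapses essentially
    nothing, so the stored starts are the sampled starts."""
    from scipy.stats import chisquare
    sizes = {"chr1": 10_000_000}
    rs = cs.sample_random_regions(sizes, None, n=10_000, length_bp=1, seed=21)
    starts = rs.intervals["start"].to_numpy()
    assert len(starts) > 9_900
    obs, _ = np.histogram(starts, bins=20, range=(0, 10_000_000))
    _, p = chisquare(obs)
    assert p > 0.01


def test_overlap_fraction_identities_and_brute_force():
    q = _bed([("chr1", i * 100, i * 100 + 50) for i in range(10)])
    assert cs.overlap_fraction(q, q) == 1.0
    shifted = q.assign(start=q["start"] + 10_000, end=q["end"] + 10_000)
    assert cs.overlap_fraction(q, shifted) == 0.0
    rng = np.random.default_rng(3)
    subj = _bed([
        ("chr1", int(s), int(s) + 40)
        for s in rng.integers(0, 1_000, size=10)
    ])
    frac = cs.overlap_fraction(q, subj)
    brute = np.mean([
        any(max(qs, ss) < min(qe, se)
            for _, ss, se in subj.itertuples(index=False))
        for _, qs, qe in q.itertuples(index=False)
    ])
    assert frac == pytest.approx(brute)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.permutations(list(range(6))))
def test_operations_invariant_to_input_order(perm):
    rows = [("chr1", 10 * i, 10 * i + 8) for i in range(6)]
    shuffled = _bed([rows[i] for i in perm])
    ref = _bed(rows)
    pd.testing.assert_frame_equal(
        cs.merge_intervals(shuffled), cs.merge_intervals(ref)
    )
    region = cs.RegionSet("r", _bed([("chr1", 0, 100)]))
    assert (
        cs.density_per_region(shuffled, [region])[0].peak_count
        == cs.density_per_region(ref, [region])[0].peak_count
    )


def test_interval_validation():
    with pytest.raises(ValueError):
        cs.merge_intervals(_bed([("chr1", 50, 50)]))
    with pytest.raises(ValueError):
        cs.merge_intervals(_bed([("chr1", -5, 50)]))
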