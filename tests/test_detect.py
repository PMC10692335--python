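"""Detection, pairing, and 3D Gaussian refinement."""

import numpy as np
import pytest

import censpa as cs
from censpa.detect import refine_center_gaussian3d, _gauss3d_model

from conftest import truth_cluster_positions


def test_noiseless_patch_yields_exactly_two_candidates():
    cfg = cs.paper_default()
    patch, _ = cs.render_particle(cfg, cs.NO_NOISE, angle_deg=25.0,
                                  separation_nm=562.0)
    cands = cs.detect_peaks(patch[1], smoothing_sigma_px=0.0,
                            threshold_quantile=0.99)
    assert len(cands) == 2


def test_constant_or_empty_image_yields_no_peaks():
    assert cs.detect_peaks(np.zeros((3, 10, 10))) == []
    assert cs.detect_peaks(np.full((3, 10, 10), 7.0)) == []


def test_spread_detection_matches_truth(small_spread):
    """>= 38 of 40 true clusters on a 20-particle noisy spread are detected
    within 2 px, with no spurious far-from-truth candidates."""
    cfg, stack, truth = small_spread
    cands = cs.detect_peaks(stack[1])
    pos = np.array([[(c.x + 0.5) * 40, (c.y + 0.5) * 40] for c in cands])
    matched = 0
    for _, row in truth.iterrows():
        for cl in truth_cluster_positions(row):
            d = np.linalg.norm(pos - cl[:2], axis=1)
            if d.min() <= 2 * cfg.pixel_pitch_nm:
                matched += 1
    assert matched >= 38


def _cand(x, y, z=4.0, inten=100.0):
    return cs.PeakCandidate(x=x, y=y, z=z, intensity=inten)


def test_pairing_simple_cases():
    # two peaks 562 nm apart -> one pair
    pairs, orphans = cs.pair_peaks([_cand(10, 10), _cand(10 + 562 / 40, 10)],
                                   40.0, 125.0)
    assert len(pairs) == 1 and not orphans
    # single peak -> zero pairs, one orphan
    pairs, orphans = cs.pair_peaks([_cand(10, 10)], 40.0, 125.0)
    assert pairs == [] and len(orphans) == 1
    # peaks closer than the gate are not paired
    pairs, orphans = cs.pair_peaks([_cand(10, 10), _cand(12, 10)], 40.0, 125.0)
    assert pairs == [] and len(orphans) == 2


def _brute_force_pairs(cands, pitch, zstep, lo=200.0, hi=1200.0):
    """Exhaustive minimum-total-distance matching over all pairings."""
    n = len(cands)
    pos = [c.position_nm(pitch, zstep) for c in cands]
    best, best_cost = [], np.inf

    def dist(i, j):
        return float(np.linalg.norm(pos[i] - pos[j]))

    idx = list(range(n))
    # enumerate all ways to partition into valid pairs (+ leftovers)
    def rec(remaining, pairs, cost):
        nonlocal best, best_cost
        score = (-len(pairs), cost)
        if not remaining or len(remaining) == 1:
            if (-len(pairs), cost) < (-len(best), best_cost):
                best, best_cost = list(pairs), cost
            return
        i = remaining[0]
        rec(remaining[1:], pairs, cost)  # i unpaired
        for j in remaining[1:]:
            d = dist(i, j)
            if lo <= d <= hi:
                rest = [k for k in remaining[1:] if k != j]
                rec(rest, pairs + [(i, j)], cost + d)

    rec(idx, [], 0.0)
    return {frozenset(p) for p in best}


def test_pairing_matches_exhaustive_matching():
    """Two well-separated doublets pair exactly as minimum-weight matching."""
    cands = [
        _cand(10.0, 10.0), _cand(10.0 + 562 / 40, 10.0),
        _cand(10.0, 140.0), _cand(10.0 + 600 / 40, 140.0),
    ]
    pairs, orphans = cs.pair_peaks(cands, 40.0, 125.0)
    got = {frozenset((cands.index(a), cands.index(b))) for a, b in pairs}
    assert got == _brute_force_pairs(cands, 40.0, 125.0)
    assert not orphans


def test_pairing_is_order_invariant():
    rng = np.random.default_rng(5)
    cands = []
    for k in range(5):
        x, y = rng.uniform(30, 400, 2)
        ang = rng.uniform(0, np.pi)
        dx, dy = 14 * np.cos(ang), 14 * np.sin(ang)
        cands.append(_cand(x, y, inten=100 + k))
        cands.append(_cand(x + dx, y + dy, inten=90 + k))
    ref = cs.pair_peaks(cands, 40.0, 125.0)[0]
    ref_set = {frozenset(((a.x, a.y), (b.x, b.y))) for a, b in ref}
    perm = list(cands)
    rng.shuffle(perm)
    got = cs.pair_peaks(perm, 40.0, 125.0)[0]
    got_set = {frozenset(((a.x, a.y), (b.x, b.y))) for a, b in got}
    assert got_set == ref_set


def _single_cluster_image(center_nm, sigma_nm=81.0, sigma_z=150.0, amp=300.0,
                          off=10.0, shape=(9, 25, 25), pitch=40.0, zstep=125.0):
    zz, yy, xx = np.meshgrid(
        (np.arange(shape[0]) + 0.5) * zstep,
        (np.arange(shape[1]) + 0.5) * pitch,
        (np.arange(shape[2]) + 0.5) * pitch,
        indexing="ij",
    )
    return _gauss3d_model(
        [amp, center_nm[0], center_nm[1], center_nm[2], sigma_nm, sigma_z, off],
        xx, yy, zz,
    )


def test_refine_recovers_offgrid_center_noiselessly():
    center = np.array([12.3 * 40, 11.7 * 40, 4.4 * 125])
    img = _single_cluster_image(center)
    fit = refine_center_gaussian3d(img, (12, 12, 4), 40.0, 125.0, window_px=11)
    assert fit.ok
    assert np.linalg.norm(fit.center_nm[:2] - center[:2]) < 0.01 * 40.0
    assert abs(fit.sigma_xy_nm - 81.0) < 0.5


def test_refine_is_translation_equivariant():
    center = np.array([12.3 * 40, 11.7 * 40, 4.4 * 125])
    img = _single_cluster_image(center, shape=(9, 31, 31))
    f0 = refine_center_gaussian3d(img, (12, 12, 4), 40.0, 125.0)
    shifted = np.roll(img, shift=(3, 2), axis=(1, 2))  # +3 rows (y), +2 cols (x)
    f1 = refine_center_gaussian3d(shifted, (14, 15, 4), 40.0, 125.0)
    delta = f1.center_nm - f0.center_nm
    assert np.allclose(delta[:2], [2 * 40.0, 3 * 40.0], atol=1e-3)


def test_refine_matches_grid_search_argmin():
    """Fit center equals exhaustive 0.05 px grid search over the same model
    family (all other parameters held at truth)."""
    center = np.array([12.31 * 40, 11.68 * 40, 4.5 * 125])
    img = _single_cluster_image(center)
    fit = refine_center_gaussian3d(img, (12, 12, 4), 40.0, 125.0, window_px=9)
    half = 4
    sub = img[:, 12 - half:12 + half + 1, 12 - half:12 + half + 1]
    zz, yy, xx = np.meshgrid(
        (np.arange(9) + 0.5) * 125.0,
        (np.arange(12 - half, 12 + half + 1) + 0.5) * 40.0,
        (np.arange(12 - half, 12 + half + 1) + 0.5) * 40.0,
        indexing="ij",
    )
    step = 0.05 * 40.0
    grid = np.arange(-1.0 * 40, 1.0 * 40 + step / 2, step)
    best, best_rss = None, np.inf
    for dx in grid:
        for dy in grid:
            model = _gauss3d_model(
                [300.0, 12.5 * 40 + dx, 12.5 * 40 + dy, center[2], 81.0, 150.0, 10.0],
                xx, yy, zz,
            )
            rss = float(((model - sub) ** 2).sum())
            if rss < best_rss:
                best, best_rss = (12.5 * 40 + dx, 12.5 * 40 + dy), rss
    assert abs(fit.center_nm[0] - best[0]) <= step
    assert abs(fit.center_nm[1] - best[1]) <= step


def test_window_outside_image_raises():
    img = np.zeros((5, 20, 20))
    with pytest.raises(ValueError):
        refine_center_gaussian3d(img, (2, 10, 2), 40.0, 125.0, window_px=11)


def test_spread_pairing_recovers_particles(small_spread):
    """>= 95% of generated particles detected and paired; <= 2% false pairs."""
    cfg, stack, truth = small_spread
    cands = cs.detect_peaks(stack[1])
    pairs, _ = cs.pair_peaks(cands, cfg.pixel_pitch_nm, cfg.z_step_nm)
    mids = np.array(
        [
            (np.asarray(a.position_nm(40, 125)) + np.asarray(b.position_nm(40, 125))) / 2
            for a, b in pairs
        ]
    )
    true_mid = truth[["x_nm", "y_nm", "z_nm"]].to_numpy()
    hit = 0
    false_pairs = 0
    for m in mids:
        d = np.linalg.norm(true_mid[:, :2] - m[None, :2], axis=1)
        if d.min() <= 3 * cfg.pixel_pitch_nm:
            hit += 1
        else:
            false_pairs += 1
    assert hit >= 0.95 * len(truth)
    assert false_pairs <= max(1, 0.02 * len(pairs))
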