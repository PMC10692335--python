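"""Cohesin-pattern classification of centromeres.

Each particle's chromosomal-axis marker profile yields a center-enriched
ratio: mean intensity within 120 nm of the center over mean intensity in the
160-320 nm off-center band.  Particles are ranked by ascending ratio
(center-depleted first) and partitioned into split / uniform / central
classes; by default the boundaries reproduce the published rank spans
(1-200 / 201-350 / 351-463 out of 463), with an equal-thirds alternative.
A Kruskal-Wallis test (with Dunn post-hoc, Benjamini-Hochberg adjusted)
compares inter-CENP-A separations across the classes.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .align import AlignedParticle, AverageImage, sum_particles
from .profiles import Profile, extract_profile

log = logging.getLogger(__name__)

CLASS_ORDER = ("split", "uniform", "central")
# rank-span boundaries: split ranks 1-200, uniform 201-350, central 351-463
DEFAULT_BOUNDARIES = (200.0 / 463.0, 350.0 / 463.0)

CENTER_BAND_NM = 120.0
OFF_BAND_NM = (160.0, 320.0)


def center_ratio(profile: Profile, mode: str = "center_over_flank") -> float:
    """Center-enriched ratio of a chromosomal-axis profile.

    Canonical: mean intensity at |y| <= 120 nm over mean intensity at
    160 <= |y| <= 320 nm, so low ratio = center-depleted (split) and high
    ratio = center-enriched.  mode="methods_literal" returns the reciprocal
    (off-center over center).  A zero denominator gives +inf (ranked last).
    """
    pos = np.abs(np.asarray(profile.positions_nm, dtype=float))
    vals = np.asarray(profile.intensities, dtype=float)
    if pos.max() < OFF_BAND_NM[1]:
        raise ValueError("profile must cover +/-320 nm")
    center = vals[pos <= CENTER_BAND_NM].mean()
    flank = vals[(pos >= OFF_BAND_NM[0]) & (pos <= OFF_BAND_NM[1])].mean()
    if mode == "center_over_flank":
        num, den = center, flank
    elif mode == "methods_literal":
        num, den = flank, center
    else:
        raise ValueError("mode must be 'center_over_flank' or 'methods_literal'")
    if den == 0:
        return math.inf
    return float(num / den)


@dataclass
class ClassAssignment:
    particle_id: int
    center_ratio: float
    rank: int  # 1-based, ascending ratio
    label: str  # split | uniform | central


def rank_and_partition(
    ratios: dict[int, float] | pd.Series,
    boundaries: tuple[float, float] = DEFAULT_BOUNDARIES,
) -> list[ClassAssignment]:
    """Sort ascending by ratio (ties by particle id) and cut at the given
    rank fractions.  boundaries=(1/3, 2/3) gives the equal-thirds variant."""
    if isinstance(ratios, pd.Series):
        items = list(ratios.items())
    else:
        items = list(ratios.items())
    if not items:
        return []
    b1, b2 = boundaries
    if not (0.0 < b1 < b2 < 1.0):
        raise ValueError("boundaries must satisfy 0 < b1 < b2 < 1")
    items.sort(key=lambda kv: (kv[1], kv[0]))
    n = len(items)
    n1 = int(round(b1 * n))
    n2 = int(round(b2 * n))
    n1 = max(1, min(n1, n - 2)) if n >= 3 else max(0, n1)
    n2 = max(n1 + 1, min(n2, n - 1)) if n >= 3 else max(n1, n2)
    out = []
    for rank, (pid, r) in enumerate(items, start=1):
        label = "split" if rank <= n1 else ("uniform" if rank <= n2 else "central")
        out.append(ClassAssignment(pid, float(r), rank, label))
    return out


EQUAL_THIRDS = (1.0 / 3.0, 2.0 / 3.0)


def _dunn_posthoc(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-sum z tests for all class pairs, BH-adjusted."""
    labels = list(samples)
    all_vals = np.concatenate([samples[l] for l in labels])
    ranks = stats.rankdata(all_vals)
    n = len(all_vals)
    # tie correction term
    _, counts = np.unique(all_vals, return_counts=True)
    tie = (counts ** 3 - counts).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
    mean_ranks = {}
    i = 0
    for l in labels:
        k = len(samples[l])
        mean_ranks[l] = ranks[i : i + k].mean()
        i += k
    rows = []
    for a, b in itertools.combinations(labels, 2):
        na, nb = len(samples[a]), len(samples[b])
        se = math.sqrt((n * (n + 1) / 12.0 - tie) * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group1": a, "group2": b, "z": z, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df


@dataclass
class ClassSummary:
    class_sizes: dict[str, int]
    class_averages: dict[str, AverageImage]
    class_axial_profiles: dict[str, Profile]
    separation_by_class: dict[str, np.ndarray]
    kw_statistic: float | None
    kw_pvalue: float | None
    posthoc: pd.DataFrame | None


def class_summary(
    assignments: list[ClassAssignment],
    aligned: list[AlignedParticle] | None = None,
    separations_nm: dict[int, float] | None = None,
    marker_channel: int = 2,
    pitch_nm: float = 40.0,
    width_px: int = 5,
) -> ClassSummary:
    """Per-class averages, axial marker profiles, and the across-class
    Kruskal-Wallis comparison of inter-CENP-A separations.

    With fewer than two populated classes the test is skipped (logged)."""
    by_label: dict[str, list[int]] = {l: [] for l in CLASS_ORDER}
    for a in assignments:
        by_label.setdefault(a.label, []).append(a.particle_id)
    sizes = {l: len(v) for l, v in by_label.items()}

    averages: dict[str, AverageImage] = {}
    profiles: dict[str, Profile] = {}
    if aligned is not None:
        by_id: dict[int, list[AlignedParticle]] = {}
        for p in aligned:
            by_id.setdefault(p.particle_id, []).append(p)
        for label, ids in by_label.items():
            patches = [p for pid in ids for p in by_id.get(pid, [])]
            if not patches:
                continue
            avg = sum_particles(patches, pitch_nm)
            averages[label] = avg
            profiles[label] = extract_profile(
                avg.channel(marker_channel), "chromosomal", width_px, pitch_nm,
                source=f"class:{label}",
            )

    sep_by_class: dict[str, np.ndarray] = {}
    if separations_nm is not None:
        for label, ids in by_label.items():
            vals = np.array([separations_nm[i] for i in ids if i in separations_nm])
            if len(vals):
                sep_by_class[label] = vals

    kw_h = kw_p = None
    posthoc = None
    populated = [v for v in sep_by_class.values() if len(v) > 0]
    if len(populated) >= 2:
        kw_h, kw_p = stats.kruskal(*populated)
        kw_h, kw_p = float(kw_h), float(kw_p)
        posthoc = _dunn_posthoc({l: v for l, v in sep_by_class.items() if len(v)})
    else:
        log.info("class_summary: fewer than two populated classes; KW test skipped")

    return ClassSummary(
        class_sizes=sizes,
        class_averages=averages,
        class_axial_profiles=profiles,
        separation_by_class=sep_by_class,
        kw_statistic=kw_h,
        kw_pvalue=kw_p,
        posthoc=posthoc,
    )
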