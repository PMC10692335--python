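"""End-to-end single-particle-averaging pipeline.

Chains simulation (or a loaded stack) through detection, pairing, 3D
Gaussian refinement, rotational alignment, mirrored averaging, profile
fitting, geometry measurement, and (for cohesin-marker runs) center-ratio
classification.  Fully deterministic under a fixed seed; per-stage particle
attrition is logged and returned.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import align as _align
from . import classify as _classify
from . import detect as _detect
from . import geometry as _geometry
from . import profiles as _profiles
from .io import RunConfig, write_stack

log = logging.getLogger(__name__)

CENPA_CH = _geometry.CHANNELS.index("cenpa")
MARKER_CH = _geometry.CHANNELS.index("marker")


@dataclass
class PipelineResult:
    config: RunConfig
    truth: pd.DataFrame | None
    particles: list
    aligned: list
    average: _align.AverageImage | None
    report: _profiles.GeometryReport
    class_assignments: list
    class_summary: object | None
    attrition: dict

    @property
    def particle_table(self) -> pd.DataFrame:
        rows = []
        ratios = {a.particle_id: a for a in self.class_assignments}
        for p in self.particles:
            a = ratios.get(p.particle_id)
            rows.append(
                {
                    "id": p.particle_id,
                    "x1_nm": p.center1_nm[0], "y1_nm": p.center1_nm[1], "z1_nm": p.center1_nm[2],
                    "x2_nm": p.center2_nm[0], "y2_nm": p.center2_nm[1], "z2_nm": p.center2_nm[2],
                    "separation_nm": p.separation_nm,
                    "angle_deg": p.angle_deg,
                    "ratio": a.center_ratio if a else np.nan,
                    "rank": a.rank if a else -1,
                    "class": a.label if a else "",
                }
            )
        return pd.DataFrame(rows)


def analyze_stack(
    stack: np.ndarray,
    cfg: RunConfig,
    geometry_cfg: _geometry.GeometryConfig | None = None,
    truth: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run detection through classification on a (C, Z, Y, X) stack."""
    gcfg = geometry_cfg or _geometry.PRESETS[cfg.preset]()
    pitch, zstep = cfg.pixel_pitch_nm, cfg.z_step_nm
    attrition: dict[str, int] = {}

    cands = _detect.detect_peaks(
        stack[CENPA_CH],
        smoothing_sigma_px=cfg.smoothing_sigma_px,
        min_distance_px=cfg.min_distance_px,
        threshold_quantile=cfg.threshold_quantile,
    )
    attrition["detected"] = len(cands)
    pairs, orphans = _detect.pair_peaks(
        cands, pitch, zstep, cfg.min_sep_nm, cfg.max_sep_nm
    )
    attrition["paired"] = len(pairs)
    attrition["orphans"] = len(orphans)

    particles = _detect.refine_pairs(
        stack[CENPA_CH], pairs, pitch, zstep,
        window_px=cfg.refine_window_px,
        min_sep_nm=cfg.min_sep_nm, max_sep_nm=cfg.max_sep_nm,
    )
    attrition["refined"] = len(particles)
    log.info("attrition: %s", attrition)

    aligned = [
        _align.align_particle(stack, p, gcfg.crop_px, pitch, zstep) for p in particles
    ]
    attrition["aligned"] = len(aligned)

    if not particles:
        return PipelineResult(
            cfg, truth, [], [], None, _profiles.GeometryReport(), [], None, attrition
        )

    mirrored = _align.mirror_augment(aligned)
    average = _align.sum_particles(mirrored, pitch)

    cenpa_lat = _profiles.fit_gaussians(
        _profiles.extract_profile(
            average.channel(CENPA_CH), "lateral", cfg.band_width_px, pitch,
            source="avg:cenpa",
        )
    )
    marker_lat = _profiles.fit_gaussians(
        _profiles.extract_profile(
            average.channel(MARKER_CH), "lateral", cfg.band_width_px, pitch,
            source="avg:marker",
        )
    )
    marker_ax = _profiles.extract_profile(
        average.channel(MARKER_CH), "chromosomal", cfg.band_width_px, pitch,
        source="avg:marker",
    )
    seps = np.array([p.separation_nm for p in particles])
    report = _profiles.measure_geometry(
        cenpa_lateral=cenpa_lat,
        marker_lateral=marker_lat,
        marker_axial_profile=marker_ax,
        marker_kind=gcfg.marker_kind,
        separations_nm=seps,
    )

    assignments: list = []
    summary = None
    if gcfg.marker_kind == "cohesin":
        ratios = {}
        for a in aligned:
            prof = _profiles.extract_profile(
                a.patch[MARKER_CH], "chromosomal", cfg.band_width_px, pitch
            )
            ratios[a.particle_id] = _classify.center_ratio(prof)
        boundaries = (
            _classify.EQUAL_THIRDS if cfg.equal_thirds else _classify.DEFAULT_BOUNDARIES
        )
        assignments = _classify.rank_and_partition(ratios, boundaries)
        summary = _classify.class_summary(
            assignments,
            aligned=mirrored,
            separations_nm={p.particle_id: p.separation_nm for p in particles},
            marker_channel=MARKER_CH,
            pitch_nm=pitch,
            width_px=cfg.band_width_px,
        )

    return PipelineResult(
        cfg, truth, particles, aligned, average, report, assignments, summary, attrition
    )


def run_pipeline(
    cfg: RunConfig,
    stack: np.ndarray | None = None,
    geometry_cfg: _geometry.GeometryConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Simulate (when no stack is given) and analyze; optionally write the
    result bundle (CSV tables, average-image TIFF, geometry report JSON)."""
    gcfg = geometry_cfg or _geometry.PRESETS[cfg.preset]()
    truth = None
    if stack is None:
        noise = _geometry.NoiseConfig(seed=cfg.seed)
        stack, truth = _geometry.render_spread(
            cfg.n_particles, gcfg, noise, class_mix=cfg.class_mix, seed=cfg.seed
        )
    result = analyze_stack(stack, cfg, geometry_cfg=gcfg, truth=truth)

    out = out_dir or cfg.out_dir
    if out is not None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        result.particle_table.to_csv(out / "particles.csv", index=False)
        if truth is not None:
            truth.to_csv(out / "truth.csv", index=False)
        if result.average is not None:
            write_stack(
                out / "average.tif",
                result.average.image[:, None],
                cfg.pixel_pitch_nm,
                cfg.z_step_nm,
            )
        with open(out / "geometry_report.json", "w") as fh:
            json.dump(
                {
                    **{k: v for k, v in result.report.as_dict().items()},
                    "attrition": result.attrition,
                    "seed": cfg.seed,
                },
                fh,
                indent=2,
                default=lambda o: None if o is None else float(o),
            )
    return result
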