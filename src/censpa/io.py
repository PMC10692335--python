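"""Stack I/O, run configuration, and instrument presets.

Stacks are multi-page TIFF in ImageJ-compatible ZCYX order with pixel size
tags; in memory the package uses (C, Z, Y, X) float arrays.  Truth and
particle tables are CSV with documented headers.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

log = logging.getLogger(__name__)

INSTRUMENT_PRESETS = {
    "OMX": {"pixel_pitch_nm": 40.0, "z_step_nm": 125.0},
    "Elyra": {"pixel_pitch_nm": 31.0, "z_step_nm": 100.0},
}


class FormatError(ValueError):
    pass


def write_stack(
    path, stack: np.ndarray, pixel_pitch_nm: float, z_step_nm: float
) -> None:
    """Write a (C, Z, Y, X) stack as ImageJ TIFF (axes ZCYX) with resolution
    metadata in micrometres."""
    arr = np.asarray(stack, dtype=np.float32)
    if arr.ndim != 4:
        raise FormatError("write_stack expects a (C, Z, Y, X) array")
    zcyx = np.moveaxis(arr, 0, 1)
    um_per_px = pixel_pitch_nm / 1000.0
    tifffile.imwrite(
        str(path),
        zcyx,
        imagej=True,
        resolution=(1.0 / um_per_px, 1.0 / um_per_px),
        metadata={"axes": "ZCYX", "spacing": z_step_nm / 1000.0, "unit": "um"},
    )


def read_stack(
    path, pixel_pitch_nm: float | None = None, z_step_nm: float | None = None
) -> tuple[np.ndarray, dict]:
    """Read a TIFF stack into (C, Z, Y, X) plus metadata.

    Pixel pitch / z step come from the TIFF tags when present; a config
    override is used (and logged) otherwise, and a missing pitch with no
    override is an error.  A plain 2D image is accepted as a single-channel
    single-slice stack with a warning.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(str(path)) as tf:
            series = tf.series[0]
            arr = series.asarray()
            axes = series.axes
            meta_pitch = None
            meta_z = None
            page = tf.pages[0]
            res = page.tags.get("XResolution")
            if res is not None:
                num, den = res.value
                # a unit resolution (1, 1) is the writer default, not a pixel size
                if num and num != den:
                    meta_pitch = den / num * 1000.0  # um/px -> nm
            ij = tf.imagej_metadata or {}
            if "spacing" in ij:
                meta_z = float(ij["spacing"]) * 1000.0
    except (tifffile.TiffFileError, FileNotFoundError) as exc:
        raise FormatError(f"cannot read TIFF stack {path}: {exc}") from exc

    arr = np.asarray(arr)
    if arr.ndim == 2:
        warnings.warn(f"{path.name}: 2D image read as 1 channel x 1 slice")
        arr = arr[None, None]
        axes = "CZYX"
    elif arr.ndim == 3:
        # ambiguous: treat leading axis per TIFF series axes
        if axes.startswith("Z"):
            arr = arr[None]
            axes = "CZYX"
        else:
            arr = arr[:, None]
            axes = "CZYX"
    elif arr.ndim == 4:
        if axes == "ZCYX":
            arr = np.moveaxis(arr, 1, 0)
        axes = "CZYX"
    else:
        raise FormatError(f"unsupported TIFF dimensionality {arr.shape}")

    pitch = meta_pitch
    if pitch is None:
        if pixel_pitch_nm is None:
            raise FormatError(f"{path.name}: no pixel size metadata and no override")
        pitch = pixel_pitch_nm
        log.info("%s: using pixel pitch override %.3g nm", path.name, pitch)
    zs = meta_z
    if zs is None:
        zs = z_step_nm if z_step_nm is not None else 125.0
        log.info("%s: using z-step %.3g nm", path.name, zs)
    meta = {"pixel_pitch_nm": float(pitch), "z_step_nm": float(zs), "axes": axes}
    return arr.astype(float), meta


@dataclass
class RunConfig:
    """End-to-end pipeline parameters (all stage defaults in one place)."""

    preset: str = "default"  # geometry preset: default | cenpb | chr7
    instrument: str = "OMX"  # OMX: 40 nm/px, 125 nm z; Elyra: 31 nm/px, 100 nm z
    n_particles: int = 400
    seed: int = 0
    class_mix: dict | None = None
    # detection
    smoothing_sigma_px: float = 1.0
    min_distance_px: int = 3
    threshold_quantile: float = 0.999
    min_sep_nm: float = 200.0
    max_sep_nm: float = 1200.0
    refine_window_px: int = 11
    # profiles / classification
    band_width_px: int = 5
    wide_band_width_px: int = 41
    equal_thirds: bool = False
    out_dir: str | None = None

    KNOWN = None  # filled below

    def __post_init__(self) -> None:
        if self.instrument not in INSTRUMENT_PRESETS:
            raise ValueError(f"unknown instrument preset {self.instrument!r}")

    @property
    def pixel_pitch_nm(self) -> float:
        return INSTRUMENT_PRESETS[self.instrument]["pixel_pitch_nm"]

    @property
    def z_step_nm(self) -> float:
        return INSTRUMENT_PRESETS[self.instrument]["z_step_nm"]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
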