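"""Rotational alignment, cropping, mirroring, and summation of particles.

Each detected pair is rotated about its midpoint so the inter-cluster
(lateral) axis is horizontal, the z slice nearest the fitted midpoint is
extracted, and a crop_px-square patch centered on the midpoint is cut.  For
an even crop the midpoint maps to the corner shared by the four central
pixels, so patch coordinates (pixel centers at (i + 0.5 - crop/2) * pitch)
are symmetric about zero.  Because chromosome orientation on the slide is
random, profiles are computed from both original and left-right mirrored
patches; summed (not averaged) images are stored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .detect import Particle


@dataclass
class AlignedParticle:
    """Per-channel 2D patches from the center slice after rotation."""

    particle_id: int
    patch: np.ndarray  # (C, crop_px, crop_px)
    angle_deg: float
    separation_nm: float
    edge_flag: bool = False
    mirrored: bool = False


@dataclass
class AverageImage:
    """Element-wise sum of aligned patches (per channel)."""

    image: np.ndarray  # (C, crop_px, crop_px)
    n_contributing: int
    mirrored: bool
    pixel_pitch_nm: float

    def channel(self, idx: int) -> np.ndarray:
        return self.image[idx]


def patch_positions_nm(crop_px: int, pitch_nm: float) -> np.ndarray:
    """Pixel-center coordinates of a crop, relative to the patch center."""
    return (np.arange(crop_px) + 0.5 - crop_px / 2.0) * pitch_nm


def align_particle(
    stack: np.ndarray,
    particle: Particle,
    crop_px: int,
    pitch_nm: float,
    z_step_nm: float,
    order: int = 3,
) -> AlignedParticle:
    """Rotate by -angle about the midpoint, translate the midpoint to the
    crop center, and cut the center z slice for every channel.

    Interpolation is cubic spline by default (order=1 gives monotone bilinear
    resampling); at the cluster widths produced by 3D-SIM the spline's
    residual is an order of magnitude below bilinear with no visible ringing.
    Patches that sample outside the field are zero-padded and edge-flagged.
    """
    nchan, nz, ny, nx = stack.shape
    mid = particle.midpoint_nm
    z_idx = int(np.clip(round(mid[2] / z_step_nm - 0.5), 0, nz - 1))
    theta = np.radians(particle.angle_deg)
    c, s = np.cos(theta), np.sin(theta)

    # output pixel (row j, col i) center in patch frame (nm, relative to midpoint)
    # maps to field position midpoint + R(theta) @ (x_out, y_out).
    # affine_transform computes input_coords = matrix @ output_coords + offset
    # in (row, col) index units; pixel i has center (i + 0.5) * pitch, i.e.
    # index = pos / pitch - 0.5.
    half = crop_px / 2.0
    # x_out = (i + 0.5 - half) * pitch ; y_out = (j + 0.5 - half) * pitch
    # x_in = mx + c * x_out - s * y_out ; y_in = my + s * x_out + c * y_out
    # row_in = y_in / pitch - 0.5 ; col_in = x_in / pitch - 0.5
    matrix = np.array([[c, s], [-s, c]])  # maps (row_out, col_out) -> (row_in, col_in)
    base = np.array([0.5 - half, 0.5 - half])
    center_idx = np.array([mid[1] / pitch_nm - 0.5, mid[0] / pitch_nm - 0.5])
    # full mapping: in = matrix @ (out + base) + center_idx  (out in 0..crop-1)
    offset = matrix @ base + center_idx

    patch = np.empty((nchan, crop_px, crop_px), dtype=float)
    for k in range(nchan):
        patch[k] = ndimage.affine_transform(
            np.asarray(stack[k, z_idx], dtype=float),
            matrix,
            offset=offset,
            output_shape=(crop_px, crop_px),
            order=order,
            mode="constant",
            cval=0.0,
        )

    # edge flag: does any corner of the rotated crop leave the field?
    corners = np.array(
        [[-half, -half], [-half, half], [half, -half], [half, half]]
    ) * pitch_nm
    rot = np.array([[c, -s], [s, c]])
    field_xy = (rot @ corners.T).T + mid[:2]
    edge = bool(
        (field_xy[:, 0] < 0).any()
        or (field_xy[:, 1] < 0).any()
        or (field_xy[:, 0] > nx * pitch_nm).any()
        or (field_xy[:, 1] > ny * pitch_nm).any()
    )
    return AlignedParticle(
        particle_id=particle.particle_id,
        patch=patch,
        angle_deg=particle.angle_deg,
        separation_nm=particle.separation_nm,
        edge_flag=edge,
    )


def mirror_augment(aligned: list[AlignedParticle]) -> list[AlignedParticle]:
    """Append the left-right mirror of every patch; output is twice as long."""
    out = list(aligned)
    for a in aligned:
        out.append(
            AlignedParticle(
                particle_id=a.particle_id,
                patch=a.patch[:, :, ::-1].copy(),
                angle_deg=a.angle_deg,
                separation_nm=a.separation_nm,
                edge_flag=a.edge_flag,
                mirrored=True,
            )
        )
    return out


def sum_particles(
    aligned: list[AlignedParticle], pixel_pitch_nm: float
) -> AverageImage:
    """Element-wise per-channel sum; records the contributing count."""
    if not aligned:
        raise ValueError("sum_particles requires at least one aligned particle")
    total = np.zeros_like(aligned[0].patch)
    mirrored = False
    for a in aligned:
        total += a.patch
        mirrored = mirrored or a.mirrored
    return AverageImage(
        image=total,
        n_contributing=len(aligned),
        mirrored=mirrored,
        pixel_pitch_nm=pixel_pitch_nm,
    )
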