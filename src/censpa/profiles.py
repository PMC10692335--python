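"""Intensity profiles, multi-Gaussian fits with AIC selection, kymographs,
and the geometric quantities they carry.

Profiles are band-integrated 1D traces through an aligned patch: lateral
(perpendicular to the chromosome, through both CENP-A clusters) or
chromosomal (parallel to the chromosome, through the structure center).
The integration band is ``width_px`` pixels wide (5 px = 200 nm at the
default 40 nm pitch; a 41 px zone is used for the CENP-A axial width so the
off-axis clusters are encompassed).

Profiles are fitted with k = 1..3 Gaussians plus a constant offset; the
Akaike information criterion for least squares, AIC = n ln(RSS/n) + 2(3k+1),
selects k, with ties resolved toward fewer peaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .align import AlignedParticle, AverageImage, patch_positions_nm

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...


@dataclass
class Profile:
    positions_nm: np.ndarray  # strictly increasing, uniform spacing = pitch
    intensities: np.ndarray
    axis: str  # {"lateral", "chromosomal"}
    width_px: int
    source: str = ""

    @property
    def band_width_nm(self) -> float:
        step = float(self.positions_nm[1] - self.positions_nm[0])
        return self.width_px * step


def _band_rows(n: int, width_px: int) -> np.ndarray:
    """Indices of the width_px rows whose centers are nearest the patch
    center; ties break toward the lower index (deterministic)."""
    pos = np.arange(n) + 0.5 - n / 2.0
    order = np.lexsort((np.arange(n), np.abs(pos)))
    rows = np.sort(order[:width_px])
    return rows


def extract_profile(
    image2d: np.ndarray,
    axis: str,
    width_px: int = 5,
    pitch_nm: float = 40.0,
    source: str = "",
) -> Profile:
    """Band-integrated profile of a single-channel 2D patch.

    axis="lateral": sum over a band of rows about the chromosomal midline,
    reported against x.  axis="chromosomal": sum over a band of columns about
    the lateral midline, reported against y.  Positions are nm relative to
    the structure center.
    """
    img = np.asarray(image2d, dtype=float)
    if img.ndim != 2:
        raise ValueError("extract_profile expects a 2D patch")
    ny, nx = img.shape
    if axis == "lateral":
        if width_px > ny:
            raise ValueError("band exceeds image height")
        rows = _band_rows(ny, width_px)
        vals = img[rows, :].sum(axis=0)
        pos = patch_positions_nm(nx, pitch_nm)
    elif axis == "chromosomal":
        if width_px > nx:
            raise ValueError("band exceeds image width")
        cols = _band_rows(nx, width_px)
        vals = img[:, cols].sum(axis=1)
        pos = patch_positions_nm(ny, pitch_nm)
    else:
        raise ValueError("axis must be 'lateral' or 'chromosomal'")
    return Profile(pos, vals, axis=axis, width_px=width_px, source=source)


# -- Gaussian mixture fitting with AIC selection ------------------------

@dataclass
class GaussianFitResult:
    k: int
    centers_nm: np.ndarray
    sigmas_nm: np.ndarray
    amplitudes: np.ndarray
    offset: float
    rss: float
    aic: float
    ok: bool = True
    aic_by_k: dict = field(default_factory=dict)

    def model(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.full_like(x, self.offset)
        for c, s, a in zip(self.centers_nm, self.sigmas_nm, self.amplitudes):
            out = out + a * np.exp(-((x - c) ** 2) / (2.0 * s * s))
        return out

    @property
    def peak_to_peak_nm(self) -> float | None:
        """Distance between the outermost fitted peak centers (k >= 2)."""
        if self.k < 2:
            return None
        c = np.sort(self.centers_nm)
        return float(c[-1] - c[0])

    @property
    def central_sigma_nm(self) -> float:
        """Sigma of the peak nearest the structure center."""
        idx = int(np.argmin(np.abs(self.centers_nm)))
        return float(self.sigmas_nm[idx])

    def dominant_pair(self) -> np.ndarray | None:
        """Indices of the two largest-amplitude components (k >= 2).

        Headline pair distances use these rather than the outermost centers,
        so a small residual component (e.g. an edge artifact the AIC keeps)
        cannot masquerade as a structural peak."""
        if self.k < 2:
            return None
        return np.argsort(-self.amplitudes, kind="stable")[:2]

    @property
    def dominant_pair_distance_nm(self) -> float | None:
        idx = self.dominant_pair()
        if idx is None:
            return None
        return float(abs(self.centers_nm[idx[0]] - self.centers_nm[idx[1]]))


def _fit_k(x: np.ndarray, y: np.ndarray, k: int) -> tuple[np.ndarray, float] | None:
    span = x[-1] - x[0]
    off0 = float(np.min(y))
    amp_scale = float(np.max(y) - off0)
    if amp_scale <= 0:
        amp_scale = max(abs(float(np.max(y))), 1.0)

    # initial centers from the k largest local maxima; fall back to symmetric
    # positions when the profile exposes fewer maxima than peaks requested
    pk, props = find_peaks(y, prominence=0.0)
    if len(pk) > 0:
        order = pk[np.argsort(-y[pk], kind="stable")]
        centers0 = list(x[order[:k]])
    else:
        centers0 = []
    while len(centers0) < k:
        m = len(centers0)
        frac = (m + 1) / (k + 1)
        centers0.append(float(x[0] + frac * span))
    step = float(x[1] - x[0])
    sig0 = max(span / (6.0 * k), step)

    p0, lo, hi = [], [], []
    for c0 in centers0[:k]:
        p0 += [amp_scale, c0, sig0]
        # peaks narrower than one sample spacing are unresolvable artifacts
        lo += [0.0, float(x[0]), step]
        hi += [np.inf, float(x[-1]), float(span)]
    p0.append(off0)
    lo.append(-np.inf)
    hi.append(np.inf)

    def resid(p):
        out = np.full_like(x, p[-1])
        for i in range(k):
            a, c, s = p[3 * i : 3 * i + 3]
            out = out + a * np.exp(-((x - c) ** 2) / (2.0 * s * s))
        return out - y

    try:
        sol = least_squares(resid, p0, bounds=(lo, hi), method="trf", max_nfev=2000)
    except Exception:
        return None
    return sol.x, float(np.sum(sol.fun ** 2))


def aic_least_squares(n: int, rss: float, n_params: int) -> float:
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2.0 * n_params


def fit_gaussians(profile: Profile, k_max: int = 3) -> GaussianFitResult:
    """Fit k = 1..k_max Gaussians + offset and return the AIC-minimizing
    model.  AIC ties (ΔAIC < 1e-9) resolve to smaller k."""
    x = np.asarray(profile.positions_nm, dtype=float)
    y = np.asarray(profile.intensities, dtype=float)
    n = len(x)
    if n < 3 * k_max + 3:
        raise ValueError("profile too short for the requested model family")

    best: GaussianFitResult | None = None
    aic_by_k: dict[int, float] = {}
    # floor the RSS at the numerical noise of an exact fit so that perfect
    # models of different order tie (and the tie resolves to fewer peaks)
    rss_floor = 1e-14 * float(np.sum(y * y))
    for k in range(1, k_max + 1):
        fit = _fit_k(x, y, k)
        if fit is None:
            continue
        params, rss = fit
        aic = aic_least_squares(n, max(rss, rss_floor), 3 * k + 1)
        aic_by_k[k] = aic
        if best is None or aic < best.aic - 1e-9:
            amps = params[0 : 3 * k : 3]
            cents = params[1 : 3 * k : 3]
            sigs = params[2 : 3 * k : 3]
            order = np.argsort(cents)
            best = GaussianFitResult(
                k=k,
                centers_nm=np.asarray(cents)[order],
                sigmas_nm=np.asarray(sigs)[order],
                amplitudes=np.asarray(amps)[order],
                offset=float(params[-1]),
                rss=rss,
                aic=aic,
            )
    if best is None:
        return GaussianFitResult(
            0, np.empty(0), np.empty(0), np.empty(0), float("nan"),
            float("inf"), float("inf"), ok=False,
        )
    best.aic_by_k = aic_by_k
    return best


# -- derived geometric quantities ---------------------------------------

def fwhm(profile: Profile, baseline: float | None = None) -> float:
    """Full width at half maximum by linear interpolation of the half-max
    crossings on either side of the global maximum.  Baseline defaults to
    the profile minimum."""
    x = np.asarray(profile.positions_nm, dtype=float)
    y = np.asarray(profile.intensities, dtype=float)
    if baseline is None:
        baseline = float(y.min())
    peak = float(y.max())
    half = baseline + (peak - baseline) / 2.0
    i = int(np.argmax(y))

    def cross(idx_range) -> float | None:
        prev = None
        for j in idx_range:
            if prev is not None:
                y0, y1 = y[prev], y[j]
                if (y0 - half) * (y1 - half) <= 0 and y0 != y1:
                    t = (half - y0) / (y1 - y0)
                    return float(x[prev] + t * (x[j] - x[prev]))
            prev = j
        return None

    left = cross(range(i, -1, -1))
    right = cross(range(i, len(y)))
    if left is None or right is None:
        return float("nan")
    return right - left


def dip_width_nm(fit: GaussianFitResult, span_nm: float = 1200.0) -> float | None:
    """Width of the central depression: distance between the two maxima that
    flank the central minimum of the fitted model.  None when the fitted
    profile has no central dip."""
    x = np.linspace(-span_nm, span_nm, 4801)
    yv = fit.model(x)
    d1 = np.diff(yv)
    maxima = np.flatnonzero((d1[:-1] > 0) & (d1[1:] <= 0)) + 1
    if len(maxima) < 2:
        return None
    step = x[1] - x[0]
    refined = []
    for i in maxima:
        a, b, c = yv[i - 1], yv[i], yv[i + 1]
        denom = a - 2 * b + c
        shift = 0.5 * (a - c) / denom if denom != 0 else 0.0
        refined.append(x[i] + shift * step)
    xm = np.asarray(refined)
    left = xm[xm < 0]
    right = xm[xm > 0]
    if len(left) == 0 or len(right) == 0:
        return None
    return float(right.min() - left.max())


@dataclass
class GeometryReport:
    """Per-run geometric summary, all in nm."""

    inter_cenpa_nm: float | None = None
    cenpa_sigma_nm: float | None = None
    marker_lateral_sigma_nm: float | None = None
    marker_axial_fwhm_nm: float | None = None
    satellite_peak_offset_nm: float | None = None
    satellite_dip_width_nm: float | None = None
    per_particle_separation_mean_nm: float | None = None
    per_particle_separation_sd_nm: float | None = None
    n_particles: int = 0
    fits: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "fits"}
        return d


def measure_geometry(
    cenpa_lateral: GaussianFitResult | None = None,
    marker_lateral: GaussianFitResult | None = None,
    marker_axial_profile: Profile | None = None,
    marker_kind: str = "cohesin",
    separations_nm: np.ndarray | None = None,
) -> GeometryReport:
    """Assemble the headline geometric quantities from channel/axis fits.

    Quantities undefined for the selected model order are reported as None.
    """
    rep = GeometryReport()
    if cenpa_lateral is not None and cenpa_lateral.ok:
        rep.fits["cenpa_lateral"] = cenpa_lateral
        rep.inter_cenpa_nm = cenpa_lateral.dominant_pair_distance_nm
        idx = cenpa_lateral.dominant_pair()
        if idx is not None:
            rep.cenpa_sigma_nm = float(np.mean(cenpa_lateral.sigmas_nm[idx]))
        else:
            rep.cenpa_sigma_nm = cenpa_lateral.central_sigma_nm
    if marker_lateral is not None and marker_lateral.ok:
        rep.fits["marker_lateral"] = marker_lateral
        if marker_kind == "cohesin":
            rep.marker_lateral_sigma_nm = marker_lateral.central_sigma_nm
        else:
            d = marker_lateral.dominant_pair_distance_nm
            if d is not None:
                rep.satellite_peak_offset_nm = d / 2.0
                rep.satellite_dip_width_nm = dip_width_nm(marker_lateral)
    if marker_axial_profile is not None:
        rep.marker_axial_fwhm_nm = fwhm(marker_axial_profile)
    if separations_nm is not None and len(separations_nm) > 0:
        seps = np.asarray(separations_nm, dtype=float)
        rep.per_particle_separation_mean_nm = float(seps.mean())
        rep.per_particle_separation_sd_nm = (
            float(seps.std(ddof=1)) if len(seps) > 1 else None
        )
        rep.n_particles = int(len(seps))
    return rep


# -- kymographs ----------------------------------------------------------

@dataclass
class Kymograph:
    matrix: np.ndarray  # rows = profile positions, cols = particles (ordered)
    positions_nm: np.ndarray
    axis: str
    order: np.ndarray  # indices into the supplied particle list


def build_kymograph(
    aligned: list[AlignedParticle],
    channel: int,
    axis: str = "chromosomal",
    width_px: int = 5,
    pitch_nm: float = 40.0,
    ordering: np.ndarray | None = None,
) -> Kymograph:
    """Per-particle band-integrated profiles as columns, in the given order
    (identity by default)."""
    if not aligned:
        raise ValueError("build_kymograph requires at least one particle")
    profs = [
        extract_profile(a.patch[channel], axis, width_px, pitch_nm) for a in aligned
    ]
    order = np.arange(len(aligned)) if ordering is None else np.asarray(ordering)
    mat = np.stack([profs[i].intensities for i in order], axis=1)
    return Kymograph(
        matrix=mat, positions_nm=profs[0].positions_nm, axis=axis, order=order
    )
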