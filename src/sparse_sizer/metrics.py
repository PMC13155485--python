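"""Spatiotemporal speckle metrics X1–X4.

From a pair of co-/cross-polarized speckle movies (or the output of the
Monte Carlo engine) this module computes:

* the time-averaged, peak-normalized intensity envelopes Î∥, Î⊥;
* the 30%-of-peak iso-contour of each envelope and its geometry
  (area A, perimeter P, centroid, inner/outer radii);
* the radially averaged angular profile Î(φ) in the annulus between the
  contour's inner and outer circles (φ = 90° is the illumination
  polarization axis);
* contrast-normalized temporal intensity autocorrelations g2∥(t), g2⊥(t);

and from those the four metrics

* ``X1 = Î∥(0°) / Î∥(90°)`` — co-envelope angular anisotropy,
* ``X2 = 4πA/P²`` — cross-envelope circularity,
* ``X3 = log g2⊥ / log g2∥`` at the lag of widest channel separation,
* ``X4 = √(A/π)`` — cross-envelope equivalent contour radius (mm),

plus the cross-envelope peak-radial-fraction (radial distance of the Î⊥
maximum from the contour centroid over X4), the refractive-contrast cue.

The same code path serves experimental frame stacks and simulated
detection grids: both are reduced to (Envelope, AutocorrCurve) pairs first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as _MplPath
from scipy import ndimage
from skimage import measure

from .montecarlo import DetectionGrid

__all__ = [
    "FrameStack",
    "Envelope",
    "ContourGeometry",
    "AutocorrCurve",
    "MetricVector",
    "compute_envelope",
    "envelope_from_grid",
    "contour_at_threshold",
    "annular_angular_profile",
    "metric_X1",
    "metric_X2",
    "metric_X3",
    "metric_X4",
    "compute_g2",
    "g2_from_grid",
    "peak_radial_fraction",
    "extract_metrics",
]


@dataclass
class FrameStack:
    """One polarization channel's speckle movie.

    ``frames`` has shape (t, y, x); intensities are nonnegative and finite.
    """

    frames: np.ndarray
    frame_rate: float  # 1/s
    exposure: float  # s
    pixel_pitch: float  # mm
    channel: str  # "co" | "cross"
    polarization_axis_deg: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be (t, y, x) with at least 2 frames")
        if not np.all(np.isfinite(self.frames)) or self.frames.min() < 0:
            raise ValueError("frame intensities must be finite and nonnegative")
        if self.channel not in ("co", "cross"):
            raise ValueError("channel must be 'co' or 'cross'")


@dataclass
class Envelope:
    image: np.ndarray  # 2D in [0, 1], max exactly 1
    pixel_pitch: float  # mm
    channel: str
    polarization_axis_deg: float = 0.0
    smoothing_sigma_px: float = 0.0

    def __post_init__(self) -> None:
        if self.image.min() < 0 or not np.isclose(self.image.max(), 1.0):
            raise ValueError("envelope must be nonnegative with max 1")


@dataclass
class ContourGeometry:
    polyline: np.ndarray  # closed (N, 2) sequence of (x, y) in mm
    centroid: np.ndarray  # (2,) mm
    r_inner: float
    r_outer: float
    area_A: float  # mm^2
    perimeter_P: float  # mm

    def __post_init__(self) -> None:
        if self.area_A <= 0:
            raise ValueError("contour area must be positive")
        if self.r_inner > self.r_outer + 1e-12:
            raise ValueError("r_inner must not exceed r_outer")


@dataclass
class AutocorrCurve:
    lags: np.ndarray  # s, strictly increasing, first lag > 0
    g2: np.ndarray  # normalized, decays from ~1 toward 0
    contrast_beta: float = 1.0
    channel: str = ""

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lags) <= 0) or self.lags[0] <= 0:
            raise ValueError("lags must be strictly increasing and positive")
        if not np.all(np.isfinite(self.g2)):
            raise ValueError("g2 must be finite")


@dataclass
class MetricVector:
    X1: float
    X2: float
    X3: float
    X4: float  # mm
    t_max: float  # s
    peak_radial_fraction: float
    flags: dict = field(default_factory=dict)

    def as_array(self) -> np.ndarray:
        return np.array([self.X1, self.X2, self.X3, self.X4])


# --------------------------------------------------------------------------
# envelopes
# --------------------------------------------------------------------------


def _grain_size_px(image: np.ndarray) -> float:
    """Speckle grain size (px) from the FWHM of the spatial autocovariance
    of a single frame's fluctuation field."""
    f = image - ndimage.gaussian_filter(image, 8)
    f -= f.mean()
    ac = np.fft.irfft2(np.abs(np.fft.rfft2(f)) ** 2, s=f.shape)
    ac /= ac[0, 0]
    prof = ac[0, : image.shape[1] // 2]
    below = np.nonzero(prof < 0.5)[0]
    return float(2 * below[0]) if below.size else 2.0


def compute_envelope(stack: FrameStack, smooth: str | float = "auto") -> Envelope:
    """Temporal mean of the stack, peak-normalized (the intensity envelope).

    Finite acquisition leaves residual speckle grain on the mean image; when
    its contrast exceeds 5% (or when ``smooth`` requests it) the mean is
    low-passed with a Gaussian of σ = grain size / 2 before normalization.
    """
    mean_img = stack.frames.mean(axis=0)
    if mean_img.max() <= 0:
        raise ValueError("all-zero stack has no envelope")
    sigma = 0.0
    if smooth == "auto":
        grain = _grain_size_px(stack.frames[0])
        smooth_ref = ndimage.gaussian_filter(mean_img, max(grain, 2.0))
        core = smooth_ref > 0.3 * smooth_ref.max()
        resid = mean_img[core] / smooth_ref[core] - 1.0
        if resid.std() > 0.05:
            sigma = grain / 2.0
    elif smooth and smooth != 0:
        sigma = float(smooth)
    if sigma > 0:
        mean_img = ndimage.gaussian_filter(mean_img, sigma)
    return Envelope(
        image=mean_img / mean_img.max(),
        pixel_pitch=stack.pixel_pitch,
        channel=stack.channel,
        polarization_axis_deg=stack.polarization_axis_deg,
        smoothing_sigma_px=sigma,
    )


def envelope_from_grid(
    grid: DetectionGrid,
    channel: str,
    smooth_px: float = 1.5,
    center_mask: int = 3,
    polarization_axis_deg: float = 0.0,
) -> Envelope:
    """Envelope of a simulated detection grid.

    The ballistic/low-order entry spike concentrated at the beam axis is not
    part of the diffuse envelope; the ``center_mask`` × ``center_mask``
    block at the grid center is replaced by the median of the surrounding
    ring before smoothing and peak normalization.
    """
    img = grid.channel_intensity(channel).astype(float).copy()
    n = img.shape[0]
    c = n // 2
    if center_mask > 0:
        h = center_mask // 2
        ring = img[max(c - h - 2, 0) : c + h + 3, max(c - h - 2, 0) : c + h + 3].copy()
        ring[2 : 2 + center_mask, 2 : 2 + center_mask] = np.nan
        img[c - h : c + h + 1, c - h : c + h + 1] = np.nanmedian(ring)
    if smooth_px > 0:
        img = ndimage.gaussian_filter(img, smooth_px)
    if img.max() <= 0:
        raise ValueError(f"degenerate simulated envelope in channel {channel!r}")
    return Envelope(
        image=img / img.max(),
        pixel_pitch=grid.pixel_pitch,
        channel=channel,
        polarization_axis_deg=polarization_axis_deg,
        smoothing_sigma_px=smooth_px,
    )


# --------------------------------------------------------------------------
# contour geometry
# --------------------------------------------------------------------------


def _polygon_area_centroid(poly: np.ndarray) -> tuple[float, np.ndarray]:
    x, y = poly[:, 0], poly[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = 0.5 * cross.sum()
    if abs(area) < 1e-300:
        raise ValueError("degenerate polygon")
    cx = ((x + x1) * cross).sum() / (6.0 * area)
    cy = ((y + y1) * cross).sum() / (6.0 * area)
    return abs(area), np.array([cx, cy])


def _harmonic_smooth(poly: np.ndarray, max_harmonic: int, n_out: int = 1440) -> np.ndarray:
    """Low-pass a star-shaped closed polyline in polar harmonics.

    Residual speckle grain puts high-frequency wiggles on measured
    iso-contours that inflate the perimeter; physical diffuse envelopes have
    only low-order azimuthal structure (cos2φ / cos4φ lobes), so truncating
    r(φ) at ``max_harmonic`` removes the noise without touching the shape.
    Non-star-shaped polylines are returned unchanged.
    """
    pts = poly[:-1] if np.allclose(poly[0], poly[-1]) else poly
    _, centroid = _polygon_area_centroid(pts)
    theta = np.arctan2(pts[:, 1] - centroid[1], pts[:, 0] - centroid[0])
    r = np.hypot(pts[:, 0] - centroid[0], pts[:, 1] - centroid[1])
    order = np.argsort(theta)
    theta_s, r_s = theta[order], r[order]
    if len(np.unique(theta_s)) < len(theta_s):  # folded contour: not star-shaped
        return poly
    grid = np.linspace(-np.pi, np.pi, n_out, endpoint=False)
    r_grid = np.interp(grid, theta_s, r_s, period=2 * np.pi)
    spec = np.fft.rfft(r_grid)
    spec[max_harmonic + 1 :] = 0.0
    r_smooth = np.fft.irfft(spec, n=n_out)
    out = np.column_stack(
        [centroid[0] + r_smooth * np.cos(grid), centroid[1] + r_smooth * np.sin(grid)]
    )
    return np.vstack([out, out[:1]])


def contour_at_threshold(
    env: Envelope, level: float = 0.30, max_harmonic: int | None = 12
) -> ContourGeometry:
    """Subpixel iso-contour of the envelope at ``level`` × peak.

    Among closed contours, the one enclosing the global maximum is kept
    (satellite contours are noise); holes are ignored.  Geometry is reported
    in mm via the pixel pitch.  ``max_harmonic`` applies polar harmonic
    de-noising to the polyline (None disables it).
    """
    img = env.image
    if not (img.min() < level < img.max()):
        raise ValueError(
            f"no {level:.0%} contour: envelope range [{img.min():.3g}, {img.max():.3g}]"
        )
    contours = measure.find_contours(img, level)
    peak_rc = np.unravel_index(np.argmax(img), img.shape)
    peak_xy = np.array([peak_rc[1], peak_rc[0]], dtype=float)
    best = None
    best_area = -1.0
    for c in contours:
        if len(c) < 4 or not np.allclose(c[0], c[-1]):
            continue  # open contour (clipped at the frame edge)
        poly_xy = np.column_stack([c[:, 1], c[:, 0]])
        if not _MplPath(poly_xy).contains_point(peak_xy):
            continue
        area_px, _ = _polygon_area_centroid(poly_xy[:-1])
        if area_px > best_area:
            best, best_area = poly_xy, area_px
    if best is None:
        raise ValueError(
            "no closed contour encloses the envelope maximum "
            "(saturated, clipped, or off-center envelope)"
        )
    poly_mm = (best + 0.5) * env.pixel_pitch  # pixel centers at (i+0.5)·pitch
    if max_harmonic is not None:
        poly_mm = _harmonic_smooth(poly_mm, max_harmonic)
    area, centroid = _polygon_area_centroid(poly_mm[:-1])
    seg = np.diff(poly_mm, axis=0)
    perimeter = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    dist = np.hypot(poly_mm[:-1, 0] - centroid[0], poly_mm[:-1, 1] - centroid[1])
    return ContourGeometry(
        polyline=poly_mm,
        centroid=centroid,
        r_inner=float(dist.min()),
        r_outer=float(dist.max()),
        area_A=float(area),
        perimeter_P=perimeter,
    )


def annular_angular_profile(
    env: Envelope,
    geom: ContourGeometry,
    bin_deg: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean envelope intensity per azimuth bin in the annulus
    r_inner ≤ r ≤ r_outer around the contour centroid.

    Returns (bin centers in degrees, profile).  φ = 90° is the direction of
    the illumination polarization axis; empty bins are interpolated from
    their neighbors.  A degenerate annulus (r_inner ≈ r_outer, circular
    contour) is widened to one pixel pitch.
    """
    ny, nx = env.image.shape
    xs = (np.arange(nx) + 0.5) * env.pixel_pitch - geom.centroid[0]
    ys = (np.arange(ny) + 0.5) * env.pixel_pitch - geom.centroid[1]
    X, Y = np.meshgrid(xs, ys)
    R = np.hypot(X, Y)
    r_lo, r_hi = geom.r_inner, geom.r_outer
    if r_hi - r_lo < env.pixel_pitch:
        pad = (env.pixel_pitch - (r_hi - r_lo)) / 2 + 1e-9
        r_lo, r_hi = max(r_lo - pad, 0.0), r_hi + pad
    mask = (R >= r_lo) & (R <= r_hi)
    phi = (np.degrees(np.arctan2(Y, X)) - env.polarization_axis_deg + 90.0) % 360.0
    n_bins = int(round(360.0 / bin_deg))
    idx = np.minimum((phi[mask] / bin_deg).astype(int), n_bins - 1)
    sums = np.bincount(idx, weights=env.image[mask], minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    profile = np.full(n_bins, np.nan)
    nz = counts > 0
    profile[nz] = sums[nz] / counts[nz]
    if not nz.all():  # interpolate empty bins periodically
        centers = np.arange(n_bins)
        profile = np.interp(
            centers, centers[nz], profile[nz], period=n_bins
        )
    return (np.arange(n_bins) + 0.5) * bin_deg, profile


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------


def _profile_at(
    bins: np.ndarray, profile: np.ndarray, angle: float, half_window_deg: float = 9.0
) -> float:
    """Profile value at ``angle``: mean over ±``half_window_deg`` around the
    angle and its 180°-opposite.  The window average suppresses speckle
    noise; for the low-order (cos2φ/cos4φ) physical profiles a ±9° window
    biases the modulation by < 1%."""
    sel = np.zeros(len(bins), dtype=bool)
    for a in (angle, angle + 180.0):
        d = np.abs((bins - a + 180.0) % 360.0 - 180.0)
        sel |= d <= half_window_deg
    return float(profile[sel].mean())


def metric_X1(bins: np.ndarray, profile: np.ndarray) -> float:
    """X1 = Î∥(φ=0°) / Î∥(φ=90°) from the annular angular profile."""
    denom = _profile_at(bins, profile, 90.0)
    if denom <= 0:
        raise ValueError("malformed envelope: zero intensity at 90 degrees")
    return _profile_at(bins, profile, 0.0) / denom


def metric_X2(geom: ContourGeometry) -> float:
    """Circularity X2 = 4πA/P² of the cross-envelope contour."""
    return 4.0 * np.pi * geom.area_A / geom.perimeter_P**2


def metric_X4(geom: ContourGeometry) -> float:
    """Equivalent contour radius X4 = √(A/π), in mm."""
    return float(np.sqrt(geom.area_A / np.pi))


def metric_X3(
    g2_co: AutocorrCurve,
    g2_cross: AutocorrCurve,
    band: tuple[float, float] = (0.05, 0.95),
    n_lags: int = 64,
    mode: str = "separation",
    noise_floor: float = 0.01,
) -> tuple[float, float, bool]:
    """X3 = log g2⊥ / log g2∥ at t_max; returns (X3, t_max, degenerate).

    Both curves are resampled onto a common geometric lag grid.  t_max is
    the lag of widest vertical separation |g2∥ − g2⊥| restricted to lags
    where both curves lie within ``band`` (``mode="derivative"`` instead
    uses the lag where the co-curve's |dg2/dlog t| peaks).  When the curves
    never separate beyond ``noise_floor``, X3 = 1 with the degenerate flag.
    """
    lo = max(g2_co.lags[0], g2_cross.lags[0])
    hi = min(g2_co.lags[-1], g2_cross.lags[-1])
    lags = np.geomspace(lo, hi, n_lags)
    co = np.interp(np.log(lags), np.log(g2_co.lags), g2_co.g2)
    cx = np.interp(np.log(lags), np.log(g2_cross.lags), g2_cross.g2)
    ok = (co > band[0]) & (co < band[1]) & (cx > band[0]) & (cx < band[1])
    if not ok.any():
        return 1.0, float(lags[len(lags) // 2]), True
    if mode == "derivative":
        d = np.abs(np.gradient(co, np.log(lags)))
        d[~ok] = -np.inf
        i = int(np.argmax(d))
    else:
        sep = np.abs(co - cx)
        sep[~ok] = -np.inf
        i = int(np.argmax(sep))
    if abs(co[i] - cx[i]) < noise_floor:
        return 1.0, float(lags[i]), True
    return float(np.log(cx[i]) / np.log(co[i])), float(lags[i]), False


# --------------------------------------------------------------------------
# temporal autocorrelation
# --------------------------------------------------------------------------


def compute_g2(
    stack: FrameStack,
    max_pixels: int = 16384,
    max_lag_frac: float = 0.25,
    min_contrast: float = 0.05,
    envelope_floor: float = 0.2,
    rng_seed: int = 0,
) -> AutocorrCurve:
    """Contrast-normalized intensity autocorrelation of a speckle movie.

    The per-pixel lagged product moment ⟨I(t)I(t+τ)⟩ₜ/(⟨I(t)⟩⟨I(t+τ)⟩) is
    computed by FFT for up to ``max_pixels`` bright pixels (temporal mean
    above ``envelope_floor`` × peak), averaged over pixels, and normalized
    to start at 1 (division by the first-lag value of g2_raw − 1, i.e., the
    measured speckle contrast).
    """
    T = stack.frames.shape[0]
    if T < 64:
        raise ValueError("need at least 64 frames for the autocorrelation")
    mean_img = stack.frames.mean(axis=0)
    sel = np.nonzero(mean_img.ravel() >= envelope_floor * mean_img.max())[0]
    if sel.size > max_pixels:
        sel = np.random.default_rng(rng_seed).choice(sel, max_pixels, replace=False)
    I = stack.frames.reshape(T, -1)[:, sel].T.astype(float)  # (npix, T)

    n_lag = max(int(T * max_lag_frac), 8)
    nfft = int(2 ** np.ceil(np.log2(2 * T)))
    F = np.fft.rfft(I, n=nfft, axis=1)
    num = np.fft.irfft(F * np.conj(F), n=nfft, axis=1)[:, : n_lag + 1]
    counts = T - np.arange(n_lag + 1)
    num = num / counts  # ⟨I(t)I(t+τ)⟩_t, unbiased
    csum = np.cumsum(I, axis=1)
    tot = csum[:, -1]
    lead = np.empty((I.shape[0], n_lag + 1))
    trail = np.empty_like(lead)
    lead[:, 0] = tot / T
    trail[:, 0] = tot / T
    for tau in range(1, n_lag + 1):
        lead[:, tau] = csum[:, T - tau - 1] / (T - tau)  # mean of I[0:T-tau]
        trail[:, tau] = (tot - csum[:, tau - 1]) / (T - tau)  # mean of I[tau:T]
    g2raw = (num / (lead * trail)).mean(axis=0)
    beta = g2raw[1] - 1.0
    if beta < min_contrast:
        raise ValueError(
            f"insufficient speckle contrast (beta = {beta:.3g} < {min_contrast})"
        )
    g2 = (g2raw[1:] - 1.0) / beta
    lags = np.arange(1, n_lag + 1) / stack.frame_rate
    return AutocorrCurve(lags=lags, g2=g2, contrast_beta=float(beta), channel=stack.channel)


def g2_from_grid(grid: DetectionGrid, channel: str) -> AutocorrCurve:
    """Simulated g2(τ) = (g1(τ)/g1(0))² on the engine's lag grid."""
    g2 = grid.channel_g2(channel)
    return AutocorrCurve(
        lags=grid.time_grid[1:], g2=g2[1:], contrast_beta=1.0, channel=channel
    )


# --------------------------------------------------------------------------
# peak radial fraction and the full pipeline
# --------------------------------------------------------------------------


def peak_radial_fraction(
    env_cross: Envelope, geom: ContourGeometry, center_mask: int = 3
) -> float:
    """Radial distance of the Î⊥ global maximum from the contour centroid,
    as a fraction of X4.  The ``center_mask`` × ``center_mask`` block at the
    beam axis (image center) is excluded from the maxima search."""
    img = env_cross.image.copy()
    ny, nx = img.shape
    if center_mask > 0:
        h = center_mask // 2
        img[ny // 2 - h : ny // 2 + h + 1, nx // 2 - h : nx // 2 + h + 1] = -np.inf
    r, c = np.unravel_index(np.argmax(img), img.shape)
    xy = (np.array([c, r]) + 0.5) * env_cross.pixel_pitch
    dist = float(np.hypot(*(xy - geom.centroid)))
    return dist / metric_X4(geom)


def _to_envelope_and_g2(source, channel, **kw):
    if isinstance(source, DetectionGrid):
        env = envelope_from_grid(
            source,
            channel,
            smooth_px=kw.get("sim_smooth_px", 1.5),
            polarization_axis_deg=kw.get("polarization_axis_deg", 0.0),
        )
        return env, g2_from_grid(source, channel)
    if isinstance(source, FrameStack):
        if source.channel != channel:
            raise ValueError(f"expected a {channel!r} stack, got {source.channel!r}")
        return compute_envelope(source, smooth=kw.get("smooth", "auto")), compute_g2(
            source, rng_seed=kw.get("rng_seed", 0)
        )
    raise TypeError(f"unsupported input type {type(source).__name__}")


def extract_metrics(co, cross, level: float = 0.30, **kw) -> MetricVector:
    """Full metric extraction: envelopes → contours → X1/X2/X4 and
    peak-radial-fraction, autocorrelations → X3.

    ``co`` and ``cross`` may each be a FrameStack or a (shared) simulated
    DetectionGrid; the code path is identical past envelope/g2 construction.
    """
    env_co, g2_co = _to_envelope_and_g2(co, "co", **kw)
    env_cx, g2_cx = _to_envelope_and_g2(cross, "cross", **kw)

    flags: dict = {}
    max_harmonic = kw.get("max_harmonic", 12)
    geom_co = contour_at_threshold(env_co, level, max_harmonic=max_harmonic)
    bins, profile = annular_angular_profile(env_co, geom_co, kw.get("bin_deg", 2.0))
    x1 = metric_X1(bins, profile)

    geom_cx = contour_at_threshold(env_cx, level, max_harmonic=max_harmonic)
    x2 = metric_X2(geom_cx)
    x4 = metric_X4(geom_cx)
    frac = peak_radial_fraction(env_cx, geom_cx)

    x3, t_max, degenerate = metric_X3(
        g2_co, g2_cx, mode=kw.get("t_max_mode", "separation")
    )
    if degenerate:
        flags["degenerate_separation"] = True
    return MetricVector(
        X1=x1, X2=x2, X3=x3, X4=x4, t_max=t_max, peak_radial_fraction=frac, flags=flags
    )
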