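"""Single-channel spot detection: seeding, elliptical Gaussian fits, filtering.

The detection procedure mirrors classical single-molecule localization:

1. Robust background subtraction (image median; spread via the scaled
   median absolute deviation) followed by threshold zeroing.
2. Candidate seeding at convergence points of the image gradient vector
   field — pixels toward which the surrounding normalized gradient
   vectors point — with at most one candidate per connected bright region.
3. Refinement of each candidate by a least-squares fit of a rotated
   elliptical 2D Gaussian plus constant background over a small window.
4. Filtering on circularity (major/minor axis ratio of the fitted
   ellipse) and on integrated brightness relative to the per-image median,
   which removes dim noise, aggregates and misshapen or overlapping spots.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "DetectionConfig",
    "Particle",
    "ParticleStatus",
    "RejectReason",
    "seed_candidates",
    "fit_spot",
    "filter_particles",
    "intensity_histogram",
    "detect_particles",
    "robust_background",
]

MAD_SCALE = 1.4826  # MAD -> sd for a normal distribution


class ParticleStatus(Enum):
    ACCEPTED = "ACCEPTED"
    REJECTED = "REJECTED"


class RejectReason(Enum):
    NONE = "NONE"
    TOO_BRIGHT = "TOO_BRIGHT"
    TOO_DIM = "TOO_DIM"
    NON_CIRCULAR = "NON_CIRCULAR"
    EDGE = "EDGE"
    FIT_FAILED = "FIT_FAILED"


@dataclass(frozen=True)
class DetectionConfig:
    """Detection, fitting and filtering parameters.

    ``threshold_k`` scales the robust background sd for threshold
    subtraction. Brightness bounds are expressed as multiples of the
    scaled MAD of accepted integrated intensities around their median.
    ``threshold_floor_frac`` sets a minimum threshold as a fraction of the
    smoothed background-subtracted peak, so that exactly-noiseless images
    (robust sd = 0) still segment into separate bright regions.
    """

    threshold_k: float = 3.0
    fit_window_px: int = 11
    circularity_max: float = 1.5
    brightness_low: float = 5.0
    brightness_high: float = 5.0
    margin_px: int = 5
    smooth_sigma_px: float = 1.0
    sink_flux_max: float = -2.0
    threshold_floor_frac: float = 1e-2

    def __post_init__(self) -> None:
        if self.fit_window_px < 5 or self.fit_window_px % 2 == 0:
            raise ValueError("fit_window_px must be odd and >= 5")
        if self.circularity_max < 1:
            raise ValueError("circularity_max must be >= 1")
        if self.brightness_low < 0 or self.brightness_high < 0:
            raise ValueError("brightness bounds must be non-negative")
        # lower intensity bound must lie below the upper one
        if self.brightness_low + self.brightness_high <= 0:
            raise ValueError("brightness bounds must span a non-empty interval")


@dataclass(frozen=True)
class Particle:
    """A fitted spot and its accept/reject status."""

    center_x: float
    center_y: float
    amplitude: float
    sigma_major: float
    sigma_minor: float
    theta: float
    background: float
    integrated_intensity: float
    circularity: float
    status: ParticleStatus
    reject_reason: RejectReason
    channel: str = ""

    @property
    def accepted(self) -> bool:
        return self.status is ParticleStatus.ACCEPTED


def robust_background(image: np.ndarray) -> tuple[float, float]:
    """Median background level and MAD-based sd estimate of an image."""
    med = float(np.median(image))
    sd = float(MAD_SCALE * np.median(np.abs(image - med)))
    return med, sd


def _gradient_sink_flux(smoothed: np.ndarray) -> np.ndarray:
    """Outward flux of the normalized gradient over the 3x3 neighbor ring.

    Strongly negative flux marks pixels toward which the surrounding
    gradient vectors converge, i.e. intensity peaks.
    """
    gy, gx = np.gradient(smoothed)
    norm = np.hypot(gx, gy)
    norm[norm == 0] = 1.0
    ux, uy = gx / norm, gy / norm
    flux = np.zeros_like(smoothed)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dx == 0 and dy == 0:
                continue
            r = float(np.hypot(dx, dy))
            # neighbor q = p + (dy, dx); outward unit vector is (dx, dy)/r
            nx = np.roll(np.roll(ux, -dy, axis=0), -dx, axis=1)
            ny = np.roll(np.roll(uy, -dy, axis=0), -dx, axis=1)
            flux += (nx * dx + ny * dy) / r
    return flux


def seed_candidates(
    image: np.ndarray, config: DetectionConfig = DetectionConfig()
) -> list[tuple[int, int]]:
    """Integer (x, y) candidate positions from gradient-field convergence.

    The image is background-subtracted and threshold-zeroed, smoothed, and
    pixels where the surrounding normalized gradient field converges are
    flagged as sinks; each connected bright region contributes at most one
    candidate (its brightest sink). Candidates closer than ``margin_px``
    to a border are dropped, and when two candidates fall within one fit
    window only the brighter survives.
    """
    image = np.asarray(image, dtype=float)
    if min(image.shape) < config.fit_window_px:
        raise ValueError("image smaller than the fit window")
    med, sd = robust_background(image)
    work = image - med
    smoothed = ndimage.gaussian_filter(work, config.smooth_sigma_px)
    peak = float(smoothed.max(initial=0.0))
    if peak <= 0:
        return []
    threshold = max(config.threshold_k * sd, config.threshold_floor_frac * peak)
    mask = smoothed > threshold
    if not mask.any():
        return []

    # sinks of the normalized gradient field cluster tightly around each
    # intensity peak; one candidate per 8-connected sink cluster
    flux = _gradient_sink_flux(smoothed)
    sinks = mask & (flux < config.sink_flux_max)
    labels, n_clusters = ndimage.label(sinks, structure=np.ones((3, 3), dtype=int))
    candidates: list[tuple[int, int, float]] = []
    for cluster in range(1, n_clusters + 1):
        ys, xs = np.nonzero(labels == cluster)
        best = np.argmax(smoothed[ys, xs])
        candidates.append((int(xs[best]), int(ys[best]), float(smoothed[ys[best], xs[best]])))

    h, w = image.shape
    m = config.margin_px
    candidates = [c for c in candidates if m <= c[0] < w - m and m <= c[1] < h - m]
    # brighter candidate wins when two fall within half a fit window
    candidates.sort(key=lambda c: -c[2])
    kept: list[tuple[int, int, float]] = []
    r2_min = (config.fit_window_px / 2) ** 2
    for c in candidates:
        if all((c[0] - k[0]) ** 2 + (c[1] - k[1]) ** 2 >= r2_min for k in kept):
            kept.append(c)
    kept.sort(key=lambda c: (c[1], c[0]))
    return [(x, y) for x, y, _ in kept]


def _elliptical_gaussian(
    params: np.ndarray, xx: np.ndarray, yy: np.ndarray
) -> np.ndarray:
    amp, x0, y0, sx, sy, theta, bg = params
    ct, st = np.cos(theta), np.sin(theta)
    xr = (xx - x0) * ct + (yy - y0) * st
    yr = -(xx - x0) * st + (yy - y0) * ct
    return amp * np.exp(-(xr**2) / (2 * sx**2) - (yr**2) / (2 * sy**2)) + bg


def _failed_particle(x: int, y: int, reason: RejectReason, channel: str) -> Particle:
    return Particle(
        center_x=float(x),
        center_y=float(y),
        amplitude=np.nan,
        sigma_major=np.nan,
        sigma_minor=np.nan,
        theta=np.nan,
        background=np.nan,
        integrated_intensity=np.nan,
        circularity=np.nan,
        status=ParticleStatus.REJECTED,
        reject_reason=reason,
        channel=channel,
    )


def fit_spot(
    image: np.ndarray,
    candidate: tuple[int, int],
    config: DetectionConfig = DetectionConfig(),
    channel: str = "",
) -> Particle:
    """Least-squares elliptical Gaussian fit around one candidate.

    The model is ``A·G(x, y; x0, y0, σ_major, σ_minor, θ) + b`` over the
    fit window; the integrated intensity is ``2π·A·σ_major·σ_minor`` and
    the circularity ``σ_major/σ_minor ≥ 1``. Candidates within
    ``margin_px`` of a border are rejected as EDGE without fitting;
    non-convergent or degenerate fits are rejected as FIT_FAILED.
    """
    image = np.asarray(image, dtype=float)
    cx, cy = int(candidate[0]), int(candidate[1])
    h, w = image.shape
    m = config.margin_px
    if not (m <= cx < w - m and m <= cy < h - m):
        return _failed_particle(cx, cy, RejectReason.EDGE, channel)

    half = config.fit_window_px // 2
    x0w, x1w = max(0, cx - half), min(w, cx + half + 1)
    y0w, y1w = max(0, cy - half), min(h, cy + half + 1)
    window = image[y0w:y1w, x0w:x1w]
    yy, xx = np.mgrid[y0w:y1w, x0w:x1w]

    border = np.concatenate([window[0], window[-1], window[1:-1, 0], window[1:-1, -1]])
    bg0 = float(np.median(border))
    amp0 = float(window[cy - y0w, cx - x0w] - bg0)
    if not np.isfinite(amp0) or amp0 <= 0 or np.ptp(window) == 0:
        return _failed_particle(cx, cy, RejectReason.FIT_FAILED, channel)
    # second-moment initial width, clamped to a sane range for the window
    wpos = np.clip(window - bg0, 0, None)
    tot = wpos.sum()
    if tot > 0:
        mx = (wpos * xx).sum() / tot
        my = (wpos * yy).sum() / tot
        var = (wpos * ((xx - mx) ** 2 + (yy - my) ** 2)).sum() / (2 * tot)
        s0 = float(np.clip(np.sqrt(max(var, 0.25)), 0.6, half / 1.5))
    else:
        s0 = 1.5

    p0 = np.array([amp0, float(cx), float(cy), s0, s0, 0.0, bg0])
    flat = window.ravel()
    xf, yf = xx.ravel(), yy.ravel()

    def residuals(p: np.ndarray) -> np.ndarray:
        return _elliptical_gaussian(p, xf, yf) - flat

    try:
        res = optimize.least_squares(
            residuals,
            p0,
            bounds=(
                [0.0, x0w - 1, y0w - 1, 0.1, 0.1, -np.pi, -np.inf],
                [np.inf, x1w, y1w, 4.0 * half, 4.0 * half, np.pi, np.inf],
            ),
            xtol=1e-8,
            ftol=1e-8,
            gtol=1e-8,
            max_nfev=200 * len(p0),
        )
    except Exception:
        return _failed_particle(cx, cy, RejectReason.FIT_FAILED, channel)
    amp, fx, fy, sx, sy, theta, bg = res.x
    if not res.success or not np.all(np.isfinite(res.x)) or sx <= 0 or sy <= 0 or amp <= 0:
        return _failed_particle(cx, cy, RejectReason.FIT_FAILED, channel)
    if sx >= sy:
        s_major, s_minor = sx, sy
    else:
        s_major, s_minor = sy, sx
        theta = theta + np.pi / 2
    theta = (theta + np.pi / 2) % np.pi - np.pi / 2  # fold into (-pi/2, pi/2]
    return Particle(
        center_x=float(fx),
        center_y=float(fy),
        amplitude=float(amp),
        sigma_major=float(s_major),
        sigma_minor=float(s_minor),
        theta=float(theta),
        background=float(bg),
        integrated_intensity=float(2 * np.pi * amp * s_major * s_minor),
        circularity=float(s_major / s_minor),
        status=ParticleStatus.ACCEPTED,
        reject_reason=RejectReason.NONE,
        channel=channel,
    )


def filter_particles(
    particles: Sequence[Particle],
    config: DetectionConfig = DetectionConfig(),
    brightness_reference: tuple[float, float] | None = None,
) -> tuple[list[Particle], list[Particle], float]:
    """Partition particles into accepted and rejected-with-reason.

    Rejections are applied in order: EDGE and FIT_FAILED (carried over
    from fitting), circularity above ``circularity_max``, then integrated
    intensity outside ``median ± k·MAD`` computed over the particles that
    survived the earlier stages (or over a frozen ``brightness_reference``
    ``(median, mad)`` pair when supplied). Returns
    ``(accepted, rejected, eliminated_fraction)``; the fraction is NaN for
    empty input.
    """
    if len(particles) == 0:
        return [], [], float("nan")

    accepted: list[Particle] = []
    rejected: list[Particle] = []
    survivors: list[Particle] = []
    for p in particles:
        if p.reject_reason in (RejectReason.EDGE, RejectReason.FIT_FAILED):
            rejected.append(p)
        elif p.circularity > config.circularity_max:
            rejected.append(
                replace(p, status=ParticleStatus.REJECTED, reject_reason=RejectReason.NON_CIRCULAR)
            )
        else:
            survivors.append(p)

    if survivors:
        if brightness_reference is None:
            intensities = np.array([p.integrated_intensity for p in survivors])
            med = float(np.median(intensities))
            mad = float(MAD_SCALE * np.median(np.abs(intensities - med)))
        else:
            med, mad = brightness_reference
        lo = med - config.brightness_low * mad
        hi = med + config.brightness_high * mad
        for p in survivors:
            if p.integrated_intensity < lo:
                rejected.append(
                    replace(p, status=ParticleStatus.REJECTED, reject_reason=RejectReason.TOO_DIM)
                )
            elif p.integrated_intensity > hi:
                rejected.append(
                    replace(p, status=ParticleStatus.REJECTED, reject_reason=RejectReason.TOO_BRIGHT)
                )
            else:
                accepted.append(
                    replace(p, status=ParticleStatus.ACCEPTED, reject_reason=RejectReason.NONE)
                )
    eliminated = len(rejected) / len(particles)
    return accepted, rejected, eliminated


def intensity_histogram(
    particles: Sequence[Particle], bin_edges: Sequence[float]
) -> tuple[np.ndarray, int, int]:
    """Histogram of accepted integrated intensities plus overflow counts.

    Returns ``(counts, n_underflow, n_overflow)``; in-range counts sum to
    the number of accepted particles minus the overflow totals. Used as a
    QC check for drifting brightness distributions (aggregation shifts the
    histogram toward brighter values).
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    vals = np.array(
        [p.integrated_intensity for p in particles if p.accepted], dtype=float
    )
    counts, _ = np.histogram(vals, bins=edges)
    n_under = int((vals < edges[0]).sum())
    n_over = int((vals > edges[-1]).sum())
    return counts, n_under, n_over


def detect_particles(
    image: np.ndarray,
    config: DetectionConfig = DetectionConfig(),
    channel: str = "",
) -> tuple[list[Particle], list[Particle], float]:
    """Full single-channel pipeline: seed, fit, filter.

    Returns ``(accepted, rejected, eliminated_fraction)``.
    """
    candidates = seed_candidates(image, config)
    fitted = [fit_spot(image, c, config, channel=channel) for c in candidates]
    return filter_particles(fitted, config)
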