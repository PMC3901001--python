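"""Cross-channel particle matching and colocalization statistics.

Particles detected independently in two (or three) color channels are
matched by mutual nearest neighbors within a distance threshold (default
1.5 px, within the 1.0-2.5 px range appropriate for diffraction-limited
spots). Percent colocalization is the matched count over the particle
count in the reference channel — systematically the channel with fewer
accepted particles — optionally normalized by the maximum colocalization
measured for a doubly labeled positive control (62% is a typical value;
the constant is per-experiment configuration, not a universal number).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .detection import Particle

__all__ = [
    "MatchConfig",
    "ColocalizationResult",
    "TriColorResult",
    "match_channels",
    "match_points",
    "percent_colocalization",
    "three_color_fraction",
]


@dataclass(frozen=True)
class MatchConfig:
    """Matching radius and scheme.

    Only mutual-nearest-neighbor matching is implemented; ties are broken
    by smaller distance, then lower particle index.
    """

    threshold_px: float = 1.5
    scheme: str = "MUTUAL_NEAREST"

    def __post_init__(self) -> None:
        if self.threshold_px <= 0:
            raise ValueError("threshold_px must be positive")
        if self.scheme != "MUTUAL_NEAREST":
            raise ValueError("only MUTUAL_NEAREST matching is supported")


@dataclass(frozen=True)
class ColocalizationResult:
    """Two-color colocalization counts and percentages for one field."""

    n_channel_a: int
    n_channel_b: int
    n_matched: int
    reference_channel: str
    percent: float
    control_max_percent: float
    normalized_percent: float
    undefined: bool = False
    over_control: bool = False


@dataclass(frozen=True)
class TriColorResult:
    """Three-color statistics: antibody spots versus dual-color particles."""

    n_antibody: int
    n_dual: int
    n_antibody_on_dual: int
    fraction_on_dual: float
    n_antibody_on_any: int
    fraction_of_all: float
    undefined: bool = False


def _centers(particles: Sequence[Particle] | np.ndarray) -> np.ndarray:
    if isinstance(particles, np.ndarray):
        pts = np.asarray(particles, dtype=float)
        if pts.size == 0:
            return pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("point array must have shape (n, 2)")
        return pts
    return np.array(
        [[p.center_x, p.center_y] for p in particles], dtype=float
    ).reshape(len(particles), 2)


def match_points(
    points_a: np.ndarray, points_b: np.ndarray, threshold_px: float
) -> list[tuple[int, int]]:
    """Mutual-nearest-neighbor pairs between two (n, 2) point sets.

    A pair (i, j) is reported when j is i's nearest neighbor in B, i is
    j's nearest in A, and their Euclidean distance is at most the
    threshold. With equidistant alternatives the lower index wins (the
    behavior of argmin over the index-ordered distance matrix). Each point
    appears in at most one pair, and the match set is invariant under
    swapping the two inputs.
    """
    a = _centers(points_a)
    b = _centers(points_b)
    if len(a) == 0 or len(b) == 0:
        return []
    d = cdist(a, b)
    nearest_b = d.argmin(axis=1)  # ties -> lower index
    nearest_a = d.argmin(axis=0)
    pairs = [
        (i, int(nearest_b[i]))
        for i in range(len(a))
        if nearest_a[nearest_b[i]] == i and d[i, nearest_b[i]] <= threshold_px
    ]
    return pairs


def match_channels(
    particles_a: Sequence[Particle] | np.ndarray,
    particles_b: Sequence[Particle] | np.ndarray,
    config: MatchConfig = MatchConfig(),
) -> list[tuple[int, int]]:
    """Match particles across two channels of the same field of view.

    Accepts particle sequences (their fitted subpixel centers are used) or
    raw (n, 2) coordinate arrays. Returns index pairs into the two inputs.
    """
    return match_points(_centers(particles_a), _centers(particles_b), config.threshold_px)


def percent_colocalization(
    particles_a: Sequence[Particle] | np.ndarray,
    particles_b: Sequence[Particle] | np.ndarray,
    pairs: Sequence[tuple[int, int]],
    control_max_percent: float = 62.0,
    channel_names: tuple[str, str] = ("a", "b"),
) -> ColocalizationResult:
    """Percent colocalization with the less-populated channel as reference.

    ``percent = 100 × n_matched / n_reference`` where the reference channel
    is the one with fewer accepted particles (ties go to channel A), and
    ``normalized_percent = 100 × percent / control_max_percent`` expresses
    the result as a fraction of the doubly-labeled-control maximum. Values
    above 100 after normalization are flagged, never clamped. An empty
    reference channel yields an undefined-flagged zero result.
    """
    n_a = len(particles_a)
    n_b = len(particles_b)
    n_matched = len(pairs)
    if n_matched > min(n_a, n_b):
        raise ValueError("more pairs than particles in a channel")
    if control_max_percent <= 0:
        raise ValueError("control_max_percent must be positive")
    ref_is_a = n_a <= n_b
    n_ref = n_a if ref_is_a else n_b
    if n_ref == 0:
        warnings.warn("reference channel empty; percent colocalization undefined")
        return ColocalizationResult(
            n_channel_a=n_a,
            n_channel_b=n_b,
            n_matched=n_matched,
            reference_channel=channel_names[0] if ref_is_a else channel_names[1],
            percent=float("nan"),
            control_max_percent=control_max_percent,
            normalized_percent=float("nan"),
            undefined=True,
        )
    percent = 100.0 * n_matched / n_ref
    normalized = 100.0 * percent / control_max_percent
    return ColocalizationResult(
        n_channel_a=n_a,
        n_channel_b=n_b,
        n_matched=n_matched,
        reference_channel=channel_names[0] if ref_is_a else channel_names[1],
        percent=percent,
        control_max_percent=control_max_percent,
        normalized_percent=normalized,
        over_control=normalized > 100.0,
    )


def dual_color_centers(
    particles_a: Sequence[Particle] | np.ndarray,
    particles_b: Sequence[Particle] | np.ndarray,
    pairs: Sequence[tuple[int, int]],
) -> np.ndarray:
    """Positions of dual-color particles: mean of the two matched centers."""
    a = _centers(particles_a)
    b = _centers(particles_b)
    if len(pairs) == 0:
        return np.empty((0, 2))
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    return 0.5 * (a[ia] + b[ib])


def three_color_fraction(
    antibody_particles: Sequence[Particle] | np.ndarray,
    dual_color_particles: Sequence[Particle] | np.ndarray,
    all_camkii_particles: Sequence[Particle] | np.ndarray,
    config: MatchConfig = MatchConfig(),
) -> TriColorResult:
    """Fraction of antibody spots colocalized with dual-color particles.

    ``fraction_on_dual`` answers whether the phospho-Thr286 antibody binds
    preferentially to holoenzymes that have already exchanged subunits
    (dual-color particles): antibody spots are matched against the dual
    particles' mean centers. ``fraction_of_all`` reports the antibody
    colocalization against all kinase particles, the quantity followed
    over a time course. Undefined (NaN, flagged) with no antibody spots.
    """
    ab = _centers(antibody_particles)
    dual = _centers(dual_color_particles)
    allp = _centers(all_camkii_particles)
    n_ab = len(ab)
    if n_ab == 0:
        warnings.warn("no antibody particles; three-color fractions undefined")
        return TriColorResult(0, len(dual), 0, float("nan"), 0, float("nan"), undefined=True)
    on_dual = match_points(ab, dual, config.threshold_px)
    on_any = match_points(ab, allp, config.threshold_px)
    return TriColorResult(
        n_antibody=n_ab,
        n_dual=len(dual),
        n_antibody_on_dual=len(on_dual),
        fraction_on_dual=len(on_dual) / n_ab,
        n_antibody_on_any=len(on_any),
        fraction_of_all=len(on_any) / n_ab,
    )
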