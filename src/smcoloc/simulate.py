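"""Synthetic two-pool subunit-exchange experiment and TIRF field renderer.

This module simulates the mixing experiment end to end:

1. Two pools of dodecameric CaMKII holoenzymes are labeled with spectrally
   distinct dyes (one color per pool), with a per-subunit labeling
   probability and a dark-fluorophore fraction folded into a single
   visible-label probability at t = 0.
2. Activation gates stochastic exchange of subunits between holoenzymes:
   each event swaps one "vertical dimer" (a contiguous two-subunit unit,
   configurable down to a single subunit) between an activated donor and a
   random acceptor, with exponential waiting times.
3. A random subsample of the population is immobilized on a simulated field
   of view and rendered into per-channel images with Gaussian point-spread
   functions, Poisson shot noise and Gaussian read noise, together with a
   ground-truth table for recovery tests.

All randomness flows through explicit seeds; there is no hidden global RNG.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SubunitColor",
    "Holoenzyme",
    "Population",
    "MixingConfig",
    "FieldSpec",
    "GroundTruthRecord",
    "simulate_mixing",
    "true_colocalization_fraction",
    "ground_truth_colocalization",
    "population_with_dual_fraction",
    "render_field",
]

N_SUBUNITS = 12  # dodecamer; tetradecamers are out of scope
N_DIMERS = N_SUBUNITS // 2


class SubunitColor(Enum):
    """Visible label state of one subunit.

    A subunit is UNLABELED if it carries no dye or a dye in a dark state;
    only visible fluorophores are tracked.
    """

    UNLABELED = 0
    RED = 1
    GREEN = 2


# integer codes used in the vectorized population arrays
_UNLABELED, _RED, _GREEN = 0, 1, 2


@dataclass(frozen=True)
class Holoenzyme:
    """One dodecameric holoenzyme.

    Subunits are ordered as six contiguous "vertical dimers": subunits
    (2i, 2i+1) form dimer i, the proposed unit of release and capture.
    """

    id: int
    subunit_colors: tuple[SubunitColor, ...]
    activated: bool
    pT286: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.subunit_colors) != N_SUBUNITS:
            raise ValueError(f"holoenzyme must have {N_SUBUNITS} subunits")
        if len(self.pT286) != N_SUBUNITS:
            raise ValueError(f"pT286 must have {N_SUBUNITS} entries")
        if not all(isinstance(c, SubunitColor) for c in self.subunit_colors):
            raise ValueError("subunit colors must be SubunitColor values")

    @property
    def n_red(self) -> int:
        return sum(c is SubunitColor.RED for c in self.subunit_colors)

    @property
    def n_green(self) -> int:
        return sum(c is SubunitColor.GREEN for c in self.subunit_colors)

    @property
    def n_pT286(self) -> int:
        return sum(self.pT286)

    @property
    def is_dual(self) -> bool:
        return self.n_red > 0 and self.n_green > 0


class Population:
    """A population of holoenzymes stored as flat arrays for speed.

    ``colors`` is an ``(n, 12)`` uint8 array with codes 0/1/2 for
    unlabeled/red/green, ``activated`` an ``(n,)`` bool array and ``pT286``
    an ``(n, 12)`` bool array. Iteration yields :class:`Holoenzyme` views.
    """

    def __init__(
        self,
        colors: np.ndarray,
        activated: np.ndarray,
        pT286: np.ndarray,
        ids: np.ndarray | None = None,
    ) -> None:
        colors = np.asarray(colors, dtype=np.uint8)
        if colors.ndim != 2 or colors.shape[1] != N_SUBUNITS:
            raise ValueError(f"colors must be (n, {N_SUBUNITS})")
        if not np.all(colors <= _GREEN):
            raise ValueError("invalid color code")
        self.colors = colors
        self.activated = np.asarray(activated, dtype=bool)
        self.pT286 = np.asarray(pT286, dtype=bool)
        n = len(colors)
        self.ids = np.arange(n) if ids is None else np.asarray(ids)
        if not (len(self.activated) == len(self.pT286) == len(self.ids) == n):
            raise ValueError("inconsistent array lengths")

    def __len__(self) -> int:
        return len(self.colors)

    def __iter__(self) -> Iterator[Holoenzyme]:
        for i in range(len(self)):
            yield self[i]

    def __getitem__(self, i: int) -> Holoenzyme:
        return Holoenzyme(
            id=int(self.ids[i]),
            subunit_colors=tuple(SubunitColor(int(c)) for c in self.colors[i]),
            activated=bool(self.activated[i]),
            pT286=tuple(bool(b) for b in self.pT286[i]),
        )

    def copy(self) -> "Population":
        return Population(
            self.colors.copy(), self.activated.copy(), self.pT286.copy(), self.ids.copy()
        )

    @classmethod
    def from_holoenzymes(cls, holos: Iterable[Holoenzyme]) -> "Population":
        holos = list(holos)
        colors = np.array(
            [[c.value for c in h.subunit_colors] for h in holos], dtype=np.uint8
        ).reshape(len(holos), N_SUBUNITS)
        activated = np.array([h.activated for h in holos], dtype=bool)
        pt = np.array([h.pT286 for h in holos], dtype=bool).reshape(len(holos), N_SUBUNITS)
        ids = np.array([h.id for h in holos])
        return cls(colors, activated, pt, ids)

    # -- per-holoenzyme summaries -------------------------------------------------
    @property
    def n_red_per_holo(self) -> np.ndarray:
        return (self.colors == _RED).sum(axis=1)

    @property
    def n_green_per_holo(self) -> np.ndarray:
        return (self.colors == _GREEN).sum(axis=1)

    def color_totals(self) -> tuple[int, int]:
        """Total (red, green) subunit counts over the whole population."""
        return int(self.n_red_per_holo.sum()), int(self.n_green_per_holo.sum())

    def dual_color_fraction(self) -> float:
        """Fraction of all holoenzymes carrying at least one of each color."""
        dual = (self.n_red_per_holo > 0) & (self.n_green_per_holo > 0)
        return float(dual.mean())


@dataclass(frozen=True)
class MixingConfig:
    """Conditions of the two-pool mixing experiment.

    ``label_prob`` is the per-subunit dye-attachment probability (the assay
    works at 20-40% labeling efficiency; default 0.3) and ``dark_prob`` the
    fraction of attached dyes that never emit; only their product matters,
    so both are folded into one visible-label probability at t = 0.
    ``k_ex`` is the exchange-event rate per activated holoenzyme per minute
    (a free parameter — no rate law is established for this process).
    """

    n_red: int
    n_green: int
    seed: int
    label_prob: float = 0.3
    dark_prob: float = 0.2
    activated_fraction: float = 0.5
    k_ex: float = 1.0
    duration_min: float = 60.0
    exchange_unit: str = "dimer"  # "dimer" (vertical dimer) or "monomer"
    acceptor_unactivated_only: bool = False

    def __post_init__(self) -> None:
        if self.n_red < 0 or self.n_green < 0:
            raise ValueError("pool sizes must be non-negative")
        if self.n_red + self.n_green == 0:
            raise ValueError("population must contain at least one holoenzyme")
        for name in ("label_prob", "dark_prob", "activated_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.k_ex < 0:
            raise ValueError("k_ex must be non-negative")
        if self.duration_min < 0:
            raise ValueError("duration must be non-negative")
        if self.exchange_unit not in ("dimer", "monomer"):
            raise ValueError("exchange_unit must be 'dimer' or 'monomer'")

    @property
    def visible_prob(self) -> float:
        return self.label_prob * (1.0 - self.dark_prob)


def _initial_population(config: MixingConfig, rng: np.random.Generator) -> Population:
    n = config.n_red + config.n_green
    colors = np.zeros((n, N_SUBUNITS), dtype=np.uint8)
    visible = rng.random((n, N_SUBUNITS)) < config.visible_prob
    colors[: config.n_red][visible[: config.n_red]] = _RED
    colors[config.n_red :][visible[config.n_red :]] = _GREEN

    activated = np.zeros(n, dtype=bool)
    n_act = int(round(config.activated_fraction * n))
    activated[rng.choice(n, size=n_act, replace=False)] = True
    # activated holoenzymes start fully autophosphorylated at Thr286;
    # exchange then carries pT286 subunits into unactivated acceptors
    pt = np.zeros((n, N_SUBUNITS), dtype=bool)
    pt[activated] = True
    return Population(colors, activated, pt)


def _apply_exchange_events(
    pop: Population, n_events: int, config: MixingConfig, rng: np.random.Generator
) -> None:
    """Apply ``n_events`` dimer (or monomer) swap events in place."""
    donors_pool = np.flatnonzero(pop.activated)
    if donors_pool.size == 0 or n_events == 0:
        return
    n = len(pop)
    if config.acceptor_unactivated_only:
        acceptors_pool = np.flatnonzero(~pop.activated)
        if acceptors_pool.size == 0:
            return
    else:
        acceptors_pool = None  # any holoenzyme other than the donor

    unit = 2 if config.exchange_unit == "dimer" else 1
    n_units = N_SUBUNITS // unit
    donors = rng.choice(donors_pool, size=n_events)
    du = rng.integers(0, n_units, size=n_events)
    au = rng.integers(0, n_units, size=n_events)
    for k in range(n_events):
        d = donors[k]
        if acceptors_pool is not None:
            a = int(rng.choice(acceptors_pool))
            if a == d:
                continue
        else:
            a = int(rng.integers(0, n - 1))
            if a >= d:
                a += 1
        ds = slice(du[k] * unit, du[k] * unit + unit)
        as_ = slice(au[k] * unit, au[k] * unit + unit)
        pop.colors[d, ds], pop.colors[a, as_] = (
            pop.colors[a, as_].copy(),
            pop.colors[d, ds].copy(),
        )
        pop.pT286[d, ds], pop.pT286[a, as_] = (
            pop.pT286[a, as_].copy(),
            pop.pT286[d, ds].copy(),
        )


def simulate_mixing(
    config: MixingConfig, times: Sequence[float] | None = None
) -> dict[float, Population]:
    """Simulate the mixing experiment and return population snapshots.

    Exchange events occur on a memoryless clock with aggregate rate
    ``k_ex × (number of activated holoenzymes)`` per minute; each event
    swaps one exchange unit between a random activated donor and a random
    acceptor, conserving per-color subunit totals exactly.

    Parameters
    ----------
    config
        Experiment conditions; ``config.seed`` drives all randomness.
    times
        Snapshot times in minutes (default: ``[config.duration_min]``).
        Times beyond ``duration_min`` are rejected.

    Returns
    -------
    dict mapping each requested time to an independent Population snapshot.
    """
    if times is None:
        times = [config.duration_min]
    times = sorted(float(t) for t in times)
    if times and times[0] < 0:
        raise ValueError("snapshot times must be non-negative")
    if times and times[-1] > config.duration_min:
        raise ValueError("snapshot times must not exceed duration_min")

    rng = np.random.default_rng(config.seed)
    pop = _initial_population(config, rng)
    n_act = int(pop.activated.sum())
    rate = config.k_ex * n_act  # events per minute, constant over time

    # draw the full event-time sequence up front (exponential waiting times)
    if rate > 0 and config.duration_min > 0:
        n_expected = rate * config.duration_min
        event_times: list[float] = []
        t = 0.0
        # draw in blocks to avoid a per-event Python call to the RNG
        block = max(64, int(n_expected + 6 * np.sqrt(n_expected) + 10))
        while True:
            waits = rng.exponential(1.0 / rate, size=block)
            ts = t + np.cumsum(waits)
            inside = ts[ts <= config.duration_min]
            event_times.extend(inside.tolist())
            if inside.size < block:
                break
            t = ts[-1]
    else:
        event_times = []

    snapshots: dict[float, Population] = {}
    ev = 0
    for t_snap in times:
        n_due = int(np.searchsorted(np.asarray(event_times), t_snap, side="right"))
        _apply_exchange_events(pop, n_due - ev, config, rng)
        ev = n_due
        snapshots[t_snap] = pop.copy()
    return snapshots


def _as_population(population: Population | Iterable[Holoenzyme]) -> Population:
    if isinstance(population, Population):
        return population
    return Population.from_holoenzymes(population)


def true_colocalization_fraction(population: Population | Iterable[Holoenzyme]) -> float:
    """Ground-truth analogue of the imaging colocalization statistic.

    Returns the number of dual-color holoenzymes (at least one visible red
    and one visible green subunit) divided by the number of holoenzymes
    containing the rarer color, mirroring the reference-channel convention
    of the imaging analysis. All dual particles count equally regardless of
    how many subunits were exchanged.

    Returns NaN (with a warning) when no holoenzyme carries any label.
    """
    pop = _as_population(population)
    if len(pop) == 0:
        raise ValueError("population is empty")
    has_red = pop.n_red_per_holo > 0
    has_green = pop.n_green_per_holo > 0
    n_red_h = int(has_red.sum())
    n_green_h = int(has_green.sum())
    denom = min(n_red_h, n_green_h) if (n_red_h and n_green_h) else max(n_red_h, n_green_h)
    if denom == 0:
        warnings.warn("no labeled holoenzymes; colocalization fraction undefined")
        return float("nan")
    return float(int((has_red & has_green).sum()) / denom)


def population_with_dual_fraction(
    n: int,
    dual_fraction: float,
    seed: int,
    visible_prob: float = 0.24,
) -> Population:
    """Construct a population with a prescribed share of dual-color holoenzymes.

    Used to set up end-to-end recovery experiments at controlled ground
    truth: ``dual_fraction`` of the holoenzymes have six subunits eligible
    for each color, the rest are single-color, and each eligible subunit is
    visibly labeled with probability ``visible_prob`` (default 0.24, i.e.
    30% labeling with a 20% dark fraction). The realized dual-color
    fraction differs from the request through labeling stochasticity; read
    it off the returned population, not the argument.
    """
    if not 0.0 <= dual_fraction <= 1.0:
        raise ValueError("dual_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_dual = int(round(dual_fraction * n))
    n_single = n - n_dual
    n_red_only = n_single // 2
    colors = np.zeros((n, N_SUBUNITS), dtype=np.uint8)
    vis = rng.random((n, N_SUBUNITS)) < visible_prob
    colors[:n_dual, : N_SUBUNITS // 2][vis[:n_dual, : N_SUBUNITS // 2]] = _RED
    colors[:n_dual, N_SUBUNITS // 2 :][vis[:n_dual, N_SUBUNITS // 2 :]] = _GREEN
    colors[n_dual : n_dual + n_red_only][vis[n_dual : n_dual + n_red_only]] = _RED
    colors[n_dual + n_red_only :][vis[n_dual + n_red_only :]] = _GREEN
    activated = np.zeros(n, dtype=bool)
    pt = np.zeros((n, N_SUBUNITS), dtype=bool)
    return Population(colors, activated, pt)


@dataclass(frozen=True)
class FieldSpec:
    """Geometry, optics and noise of one simulated field of view.

    ``unit_brightness`` is the expected integrated count contributed by one
    visible fluorophore; ``background`` the expected counts per pixel. Shot
    noise is Poisson on signal + background; read noise is additive
    Gaussian. Setting ``shot_noise=False`` and ``read_noise_sd=0`` gives a
    noiseless field for detector-fidelity tests. Pixel convention: 0-based,
    pixel centers at integer coordinates, x = column, y = row.
    """

    width_px: int = 512
    height_px: int = 512
    psf_sigma_px: float = 1.5
    unit_brightness: float = 2000.0
    background: float = 100.0
    read_noise_sd: float = 2.0
    n_spots: int = 100
    margin_px: int = 10
    seed: int = 0
    shot_noise: bool = True
    min_separation_px: float | None = None
    channels: tuple[str, ...] = ("red", "green")
    chromatic_offset: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    antibody_mode: str = "per_holoenzyme"  # or "per_subunit"
    antibody_label_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be positive")
        if min(self.unit_brightness, self.background, self.read_noise_sd) < 0:
            raise ValueError("intensities and noise levels must be non-negative")
        if self.n_spots < 0:
            raise ValueError("n_spots must be non-negative")
        if self.width_px - 2 * self.margin_px <= 0 or self.height_px - 2 * self.margin_px <= 0:
            raise ValueError("margin leaves no room for spots")
        if self.antibody_mode not in ("per_holoenzyme", "per_subunit"):
            raise ValueError("antibody_mode must be 'per_holoenzyme' or 'per_subunit'")


@dataclass(frozen=True)
class GroundTruthRecord:
    """True position and visible-label content of one rendered holoenzyme."""

    spot_id: int
    holoenzyme_id: int
    x_px: float
    y_px: float
    n_red_visible: int
    n_green_visible: int
    n_pT286: int


def ground_truth_records_to_frame(records: Sequence[GroundTruthRecord]) -> pd.DataFrame:
    cols = ["spot_id", "holoenzyme_id", "x_px", "y_px", "n_red_visible", "n_green_visible", "n_pT286"]
    return pd.DataFrame([[getattr(r, c) for c in cols] for r in records], columns=cols)


def ground_truth_colocalization(records: Sequence[GroundTruthRecord]) -> float:
    """Dual-color fraction of rendered spots, reference = rarer color.

    Same statistic as :func:`true_colocalization_fraction` but restricted
    to the spots actually placed on the field, so that end-to-end tests
    compare the detector against exactly what was rendered.
    """
    red = np.array([r.n_red_visible > 0 for r in records])
    green = np.array([r.n_green_visible > 0 for r in records])
    if len(records) == 0 or not (red.any() and green.any()):
        denom = int(red.sum() + green.sum()) if len(records) else 0
        if denom == 0:
            warnings.warn("no labeled spots; colocalization undefined")
            return float("nan")
        return 0.0
    denom = min(int(red.sum()), int(green.sum()))
    return float(int((red & green).sum()) / denom)


def _draw_positions(spec: FieldSpec, rng: np.random.Generator) -> np.ndarray:
    lo_x, hi_x = spec.margin_px, spec.width_px - 1 - spec.margin_px
    lo_y, hi_y = spec.margin_px, spec.height_px - 1 - spec.margin_px
    if spec.min_separation_px is None:
        xs = rng.uniform(lo_x, hi_x, size=spec.n_spots)
        ys = rng.uniform(lo_y, hi_y, size=spec.n_spots)
        return np.column_stack([xs, ys])
    # rejection sampling with a minimum pairwise separation
    pts: list[tuple[float, float]] = []
    min_sq = spec.min_separation_px**2
    attempts = 0
    while len(pts) < spec.n_spots:
        attempts += 1
        if attempts > 10000 * spec.n_spots:
            raise RuntimeError("could not place spots at the requested separation")
        x = rng.uniform(lo_x, hi_x)
        y = rng.uniform(lo_y, hi_y)
        if all((x - px) ** 2 + (y - py) ** 2 >= min_sq for px, py in pts):
            pts.append((x, y))
    return np.array(pts)


def _render_channel(
    spec: FieldSpec,
    positions: np.ndarray,
    counts: np.ndarray,
    offset: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    sigma = spec.psf_sigma_px
    signal = np.zeros((spec.height_px, spec.width_px), dtype=float)
    half = int(np.ceil(5 * sigma))
    amp = counts * spec.unit_brightness / (2 * np.pi * sigma**2)
    for (x, y), a in zip(positions, amp):
        if a <= 0:
            continue
        xc, yc = x + offset[0], y + offset[1]
        x0 = max(0, int(np.floor(xc)) - half)
        x1 = min(spec.width_px, int(np.ceil(xc)) + half + 1)
        y0 = max(0, int(np.floor(yc)) - half)
        y1 = min(spec.height_px, int(np.ceil(yc)) + half + 1)
        xs = np.arange(x0, x1)
        ys = np.arange(y0, y1)
        gx = np.exp(-((xs - xc) ** 2) / (2 * sigma**2))
        gy = np.exp(-((ys - yc) ** 2) / (2 * sigma**2))
        signal[y0:y1, x0:x1] += a * np.outer(gy, gx)
    expected = signal + spec.background
    img = rng.poisson(expected).astype(float) if spec.shot_noise else expected.copy()
    if spec.read_noise_sd > 0:
        img += rng.normal(0.0, spec.read_noise_sd, size=img.shape)
    return np.clip(img, 0.0, None)


def render_field(
    sample: Population | Iterable[Holoenzyme],
    spec: FieldSpec,
    replace: bool = False,
) -> tuple[dict[str, np.ndarray], list[GroundTruthRecord]]:
    """Immobilize a random subsample on the field and image it.

    Each rendered holoenzyme contributes, in each channel, an isotropic 2D
    Gaussian of integrated intensity ``n_visible × unit_brightness``
    centered at the same subpixel position in every channel (plus any
    configured per-channel chromatic offset). Returns the per-channel
    float images and one ground-truth record per rendered holoenzyme.
    """
    pop = _as_population(sample)
    if spec.n_spots > len(pop) and not replace:
        raise ValueError(
            f"n_spots={spec.n_spots} exceeds sample size {len(pop)}; pass replace=True"
        )
    rng = np.random.default_rng(spec.seed)
    idx = rng.choice(len(pop), size=spec.n_spots, replace=replace)

    usable_area = (spec.width_px - 1 - 2 * spec.margin_px) * (
        spec.height_px - 1 - 2 * spec.margin_px
    )
    if spec.n_spots > 1:
        expected_nn = 0.5 * np.sqrt(usable_area / spec.n_spots)
        if expected_nn < 4 * spec.psf_sigma_px:
            warnings.warn(
                f"spot density high: expected nearest-neighbor distance "
                f"{expected_nn:.2f} px < 4 sigma = {4 * spec.psf_sigma_px:.2f} px"
            )

    positions = _draw_positions(spec, rng)
    n_red = pop.n_red_per_holo[idx]
    n_green = pop.n_green_per_holo[idx]
    n_pt = pop.pT286[idx].sum(axis=1)

    counts_by_channel: dict[str, np.ndarray] = {}
    for ch in spec.channels:
        if ch == "red":
            counts_by_channel[ch] = n_red.astype(float)
        elif ch == "green":
            counts_by_channel[ch] = n_green.astype(float)
        elif ch == "pT286":
            if spec.antibody_mode == "per_holoenzyme":
                labeled = (n_pt > 0) & (
                    rng.random(spec.n_spots) < spec.antibody_label_prob
                )
                counts_by_channel[ch] = labeled.astype(float)
            else:
                counts_by_channel[ch] = rng.binomial(
                    n_pt.astype(int), spec.antibody_label_prob
                ).astype(float)
        else:
            raise ValueError(f"unknown channel {ch!r}")

    images = {
        ch: _render_channel(
            spec, positions, counts, tuple(spec.chromatic_offset.get(ch, (0.0, 0.0))), rng
        )
        for ch, counts in counts_by_channel.items()
    }
    records = [
        GroundTruthRecord(
            spot_id=i,
            holoenzyme_id=int(pop.ids[idx[i]]),
            x_px=float(positions[i, 0]),
            y_px=float(positions[i, 1]),
            n_red_visible=int(n_red[i]),
            n_green_visible=int(n_green[i]),
            n_pT286=int(n_pt[i]),
        )
        for i in range(spec.n_spots)
    ]
    return images, records
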