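"""Aggregation of per-image colocalization into condition time courses.

Each time point of an experiment is imaged at several field positions;
the summary statistic is the mean normalized percent colocalization over
those images with the sample standard deviation between images as the
error bar.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["FieldSummary", "TimeCourse", "summarize_field_set", "build_timecourse",
           "fit_single_exponential"]


@dataclass(frozen=True)
class FieldSummary:
    """Mean ± sd of percent colocalization over the images of one time point."""

    time_min: float
    condition: str
    mean_percent: float
    sd_percent: float  # NaN when only one image was collected
    n_images: int


@dataclass(frozen=True)
class TimeCourse:
    """Per-condition series of field summaries, strictly increasing in time."""

    summaries: tuple[FieldSummary, ...]

    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.summaries:
            seen.setdefault(s.condition)
        return list(seen)

    def series(self, condition: str) -> list[FieldSummary]:
        return [s for s in self.summaries if s.condition == condition]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                [s.condition, s.time_min, s.mean_percent, s.sd_percent, s.n_images]
                for s in self.summaries
            ],
            columns=["condition", "time_min", "mean_percent", "sd_percent", "n_images"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TimeCourse":
        summaries = [
            FieldSummary(
                time_min=float(r.time_min),
                condition=str(r.condition),
                mean_percent=float(r.mean_percent),
                sd_percent=float(r.sd_percent),
                n_images=int(r.n_images),
            )
            for r in df.itertuples()
        ]
        return build_timecourse(summaries)


def summarize_field_set(
    per_image_percents: Sequence[float], time_min: float, condition: str
) -> FieldSummary:
    """Mean and between-image sample standard deviation for one time point.

    The sd uses the n−1 denominator and is NaN (undefined) for a single
    image.
    """
    vals = np.asarray(per_image_percents, dtype=float)
    if vals.size == 0:
        raise ValueError("at least one image value is required")
    sd = float(np.std(vals, ddof=1)) if vals.size >= 2 else float("nan")
    return FieldSummary(
        time_min=float(time_min),
        condition=condition,
        mean_percent=float(vals.mean()),
        sd_percent=sd,
        n_images=int(vals.size),
    )


def build_timecourse(summaries: Iterable[FieldSummary]) -> TimeCourse:
    """Group by condition, sort by time, reject duplicate time points."""
    summaries = list(summaries)
    seen: set[tuple[str, float]] = set()
    for s in summaries:
        key = (s.condition, s.time_min)
        if key in seen:
            raise ValueError(f"duplicate time point {s.time_min} min in condition {s.condition!r}")
        seen.add(key)
    by_condition: dict[str, list[FieldSummary]] = {}
    for s in summaries:
        by_condition.setdefault(s.condition, []).append(s)
    ordered: list[FieldSummary] = []
    for cond in by_condition:
        ordered.extend(sorted(by_condition[cond], key=lambda s: s.time_min))
    return TimeCourse(tuple(ordered))


def fit_single_exponential(
    times: Sequence[float], values: Sequence[float]
) -> tuple[float, float, float]:
    """Optional convenience fit ``v(t) = plateau·(1 − exp(−t/tau)) + v0``.

    Provided for exploratory use only; the primary deliverable of a mixing
    experiment is the raw time course, and no kinetic rate law is implied
    by this fit. Returns ``(plateau, tau, v0)``.
    """
    from scipy.optimize import curve_fit

    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 points")

    def model(t, plateau, tau, v0):
        return plateau * (1 - np.exp(-t / tau)) + v0

    span = max(v.max() - v.min(), 1e-9)
    p0 = [span, max(t.max() / 3, 1e-6), v[0]]
    popt, _ = curve_fit(model, t, v, p0=p0, maxfev=10000)
    return float(popt[0]), float(popt[1]), float(popt[2])
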