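"""File formats: 16-bit TIFF images, particle/ground-truth/result CSVs, configs."""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .colocalize import ColocalizationResult
from .detection import Particle, ParticleStatus, RejectReason
from .fret import EmissionSpectrum
from .kinetics import KineticTrace
from .simulate import GroundTruthRecord, ground_truth_records_to_frame

__all__ = [
    "write_image",
    "read_image",
    "write_ground_truth",
    "read_ground_truth",
    "particles_to_frame",
    "write_particles",
    "read_particles",
    "write_colocalization",
    "read_spectrum",
    "read_trace",
    "load_config",
]

PARTICLE_COLUMNS = [
    "channel",
    "center_x",
    "center_y",
    "amplitude",
    "sigma_major",
    "sigma_minor",
    "theta",
    "background",
    "integrated_intensity",
    "circularity",
    "status",
    "reject_reason",
]


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Save one channel as 16-bit grayscale TIFF (values clipped/rounded)."""
    arr = np.clip(np.rint(np.asarray(image, dtype=float)), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(str(path), arr.astype(np.uint16))


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=float)


def image_filename(run: str, time_min: float, channel: str) -> str:
    t = int(time_min) if float(time_min).is_integer() else time_min
    return f"{run}_t{t}_{channel}.tif"


def write_ground_truth(path: str | Path, records: Sequence[GroundTruthRecord]) -> None:
    ground_truth_records_to_frame(records).to_csv(path, index=False)


def read_ground_truth(path: str | Path) -> list[GroundTruthRecord]:
    df = pd.read_csv(path)
    return [
        GroundTruthRecord(
            spot_id=int(r.spot_id),
            holoenzyme_id=int(r.holoenzyme_id),
            x_px=float(r.x_px),
            y_px=float(r.y_px),
            n_red_visible=int(r.n_red_visible),
            n_green_visible=int(r.n_green_visible),
            n_pT286=int(r.n_pT286),
        )
        for r in df.itertuples()
    ]


def particles_to_frame(particles: Sequence[Particle]) -> pd.DataFrame:
    rows = [
        [
            p.channel,
            p.center_x,
            p.center_y,
            p.amplitude,
            p.sigma_major,
            p.sigma_minor,
            p.theta,
            p.background,
            p.integrated_intensity,
            p.circularity,
            p.status.value,
            p.reject_reason.value,
        ]
        for p in particles
    ]
    return pd.DataFrame(rows, columns=PARTICLE_COLUMNS)


def write_particles(path: str | Path, particles: Sequence[Particle]) -> None:
    particles_to_frame(particles).to_csv(path, index=False)


def read_particles(path: str | Path) -> list[Particle]:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    return [
        Particle(
            channel=str(r.channel),
            center_x=float(r.center_x),
            center_y=float(r.center_y),
            amplitude=float(r.amplitude),
            sigma_major=float(r.sigma_major),
            sigma_minor=float(r.sigma_minor),
            theta=float(r.theta),
            background=float(r.background),
            integrated_intensity=float(r.integrated_intensity),
            circularity=float(r.circularity),
            status=ParticleStatus(r.status),
            reject_reason=RejectReason(r.reject_reason),
        )
        for r in df.itertuples()
    ]


def write_colocalization(
    path: str | Path, results: Mapping[str, ColocalizationResult]
) -> None:
    """Write per-field colocalization results keyed by field id."""
    rows = [
        [
            field_id,
            r.n_channel_a,
            r.n_channel_b,
            r.n_matched,
            r.reference_channel,
            r.percent,
            r.control_max_percent,
            r.normalized_percent,
        ]
        for field_id, r in results.items()
    ]
    pd.DataFrame(
        rows,
        columns=[
            "field_id",
            "n_a",
            "n_b",
            "n_matched",
            "reference_channel",
            "percent",
            "control_max_percent",
            "normalized_percent",
        ],
    ).to_csv(path, index=False)


def read_spectrum(path: str | Path) -> EmissionSpectrum:
    """Read `wavelength_nm,intensity` CSV into an EmissionSpectrum."""
    df = pd.read_csv(path)
    return EmissionSpectrum(
        df["wavelength_nm"].to_numpy(float), df["intensity"].to_numpy(float)
    )


def read_trace(path: str | Path) -> KineticTrace:
    """Read `time_min,fluorescence_590` CSV into a KineticTrace."""
    df = pd.read_csv(path)
    return KineticTrace(
        df["time_min"].to_numpy(float), df["fluorescence_590"].to_numpy(float)
    )


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML or JSON configuration file into a plain dict."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(data, dict):
        raise ValueError(f"configuration in {path} must be a mapping")
    return data
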