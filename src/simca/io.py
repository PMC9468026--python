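"""Readers, writers, and run configuration.

Formats: multi-page 16-bit grayscale TIFF for image stacks (one page per
FOV), CSV for spot/count/sweep tables (units spelled out in column names),
JSON for transforms, calibrations, LODs and manifests, YAML for run configs.

Coordinates in all tables are 0-based pixel centers with ``x = column`` and
``y = row``, in the half-image frame of the named channel.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .colocalization import DEFAULT_COLOC_RADIUS_PX, FovCounts
from .detection import (
    DEFAULT_DENOISE_SIGMA,
    DEFAULT_THRESHOLD_MULTIPLIER,
    ImageFrame,
    SpotSet,
)
from .registration import AffineTransform2D

__all__ = [
    "FrameFormatError",
    "read_frames",
    "write_frames",
    "spots_to_frame",
    "write_spots",
    "read_spots",
    "write_counts",
    "read_counts",
    "write_transform",
    "read_transform",
    "write_ground_truth",
    "RunConfig",
]


class FrameFormatError(ValueError):
    """Raised when an image file is not 16-bit grayscale TIFF."""


def read_frames(path: str | Path) -> list[ImageFrame]:
    """Read a multi-page 16-bit grayscale TIFF as a list of frames.

    FOV ids follow page order (``fov_0``, ``fov_1``, ...); a non-16-bit or
    multi-channel page fails with an error naming the page.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(path) as tif:
            pages = list(tif.pages)
            if not pages:
                raise FrameFormatError(f"{path}: no TIFF pages")
            frames = []
            for i, page in enumerate(pages):
                arr = page.asarray()
                if arr.ndim != 2:
                    raise FrameFormatError(
                        f"{path} page {i}: expected grayscale, got shape {arr.shape}"
                    )
                if arr.dtype != np.uint16:
                    raise FrameFormatError(
                        f"{path} page {i}: expected 16-bit, got {arr.dtype}"
                    )
                frames.append(ImageFrame(pixels=arr, fov_id=f"fov_{i}"))
    except tifffile.TiffFileError as exc:
        raise FrameFormatError(f"{path}: not a readable TIFF ({exc})") from exc
    return frames


def write_frames(path: str | Path, frames: Sequence[ImageFrame]) -> None:
    """Write frames as a multi-page 16-bit grayscale TIFF, one page per FOV."""
    if not frames:
        raise ValueError("no frames to write")
    stack = np.stack([np.asarray(f.pixels, dtype=np.uint16) for f in frames])
    tifffile.imwrite(Path(path), stack, photometric="minisblack")


def spots_to_frame(spot_sets: Sequence[SpotSet]) -> pd.DataFrame:
    rows = []
    for s in spot_sets:
        for (x, y), inten in zip(s.xy, s.intensity):
            rows.append(
                {
                    "fov_id": s.fov_id,
                    "channel": s.channel,
                    "x_px": x,
                    "y_px": y,
                    "intensity_transformed": inten,
                }
            )
    return pd.DataFrame(
        rows, columns=["fov_id", "channel", "x_px", "y_px", "intensity_transformed"]
    )


def write_spots(path: str | Path, spot_sets: Sequence[SpotSet]) -> None:
    spots_to_frame(spot_sets).to_csv(path, index=False)


def read_spots(path: str | Path) -> list[SpotSet]:
    df = pd.read_csv(path)
    out = []
    for (fov, channel), g in df.groupby(["fov_id", "channel"], sort=False):
        out.append(
            SpotSet(
                fov_id=str(fov),
                channel=channel,
                xy=g[["x_px", "y_px"]].to_numpy(),
                intensity=g["intensity_transformed"].to_numpy(),
            )
        )
    return out


_COUNT_COLS = [
    "fov_id", "cab_count", "dab_count", "coloc_count",
    "normalized_coloc", "normalized_single",
    "concentration_pm", "matrix_label", "coverslip", "valid",
]


def write_counts(path: str | Path, fovs: Sequence[FovCounts]) -> None:
    pd.DataFrame([vars(f) for f in fovs])[_COUNT_COLS].to_csv(path, index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_transform(path: str | Path, t: AffineTransform2D) -> None:
    Path(path).write_text(json.dumps({"matrix": t.matrix.tolist()}, indent=2))


def read_transform(path: str | Path) -> AffineTransform2D:
    data = json.loads(Path(path).read_text())
    return AffineTransform2D(np.asarray(data["matrix"], dtype=float))


def write_ground_truth(path: str | Path, records) -> None:
    """Ground-truth CSV for simulated datasets.

    ``records`` iterates over ``(fov_id, GroundTruth)``; rows carry
    fov_id, channel, role (cab | dab_specific | dab_nonspecific), x_px, y_px,
    dyes, pair_id (index of the paired capture antibody, empty otherwise).
    """
    rows = []
    for fov_id, truth in records:
        for (x, y), dyes in zip(truth.cab_xy, truth.cab_dyes):
            rows.append((fov_id, "capture", "cab", x, y, int(dyes), ""))
        for (x, y), dyes, pair in zip(
            truth.dab_specific_xy, truth.dab_specific_dyes, truth.dab_specific_pair
        ):
            rows.append((fov_id, "detection", "dab_specific", x, y, int(dyes), int(pair)))
        for (x, y), dyes in zip(truth.dab_nonspecific_xy, truth.dab_nonspecific_dyes):
            rows.append((fov_id, "detection", "dab_nonspecific", x, y, int(dyes), ""))
    pd.DataFrame(
        rows, columns=["fov_id", "channel", "role", "x_px", "y_px", "dyes", "pair_id"]
    ).to_csv(path, index=False)


@dataclass
class RunConfig:
    """End-to-end run configuration; defaults encode the assay's constants.

    Detection: Gaussian kernel sigma 0.8 px, maxima threshold
    median + 1.2·std. Colocalization: 1.5 px. Bootstraps: 1000 iterations.
    Unknown keys in a config file are rejected rather than ignored.
    """

    # paths (None → stage skipped or synthesized)
    images: str | None = None
    labels: str | None = None  # CSV fov_id -> concentration_pm
    bead_images: str | None = None
    transform: str | None = None

    # detection
    denoise_sigma: float = DEFAULT_DENOISE_SIGMA
    threshold_multiplier: float = DEFAULT_THRESHOLD_MULTIPLIER
    reconstruction_h: float | None = None  # default: std of smoothed image
    asinh_scale: float | None = None  # default: MAD of subtracted image

    # colocalization
    coloc_radius_px: float = DEFAULT_COLOC_RADIUS_PX
    colocalization_enabled: bool = True

    # registration
    bead_match_max_distance_px: float = 5.0

    # quantification / classification
    signal_kind: str = "normalized_coloc"
    n_boot: int = 1000
    seed: int = 0
    concentrations_pm: list[float] = field(
        default_factory=lambda: [0.0, 10.0, 100.0, 300.0, 1000.0, 20000.0]
    )
    fovs_per_concentration: int = 16

    # synthetic-data overrides (SimulationConfig field name -> value)
    synthetic: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.denoise_sigma <= 0 or self.threshold_multiplier <= 0:
            raise ValueError("detection parameters must be positive")
        if self.coloc_radius_px <= 0:
            raise ValueError("coloc_radius_px must be positive")
        if self.n_boot < 1 or self.fovs_per_concentration < 1:
            raise ValueError("n_boot and fovs_per_concentration must be >= 1")
        if any(c < 0 for c in self.concentrations_pm):
            raise ValueError("concentrations must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
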