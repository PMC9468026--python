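"""Single-molecule spot detection in stitched two-channel frames.

Each frame is a 16-bit image whose left half is the capture-antibody (green)
channel and whose right half is the detection-antibody (red) channel.
Spots are diffraction-limited single molecules. The recipe runs once on the
whole stitched frame and the detected maxima are then split by half:

1. Gaussian denoising, ``sigma = 0.8`` px.
2. Background removal by morphological reconstruction: the background is the
   reconstruction by dilation of ``smoothed − h`` under ``smoothed`` and is
   subtracted, flattening uneven illumination while preserving local peaks
   (``h`` defaults to 0.8 of the maximum local spot relief, tall enough
   that real spots keep their full prominence).
3. Inverse hyperbolic sine intensity transform, ``asinh(v / s)``, compressing
   the extreme bright tail into a workable dynamic range (``s`` defaults to
   the 99.9th intensity percentile, floored at one count).
4. 8-connected local maxima kept when the transformed intensity is at least
   ``median + 1.2 · std`` of the transformed stitched image; plateaus of
   equal value collapse to one spot at their centroid. Computing the
   statistics over the stitched image lets the capture channel's dense spot
   field set a meaningful bar even when the detection half is nearly empty
   (a 0 pM control).

A per-FOV quality filter discards frames whose capture spots are not spread
over the frame (mean y further than 75 px from the vertical middle), the
signature of bubbles or large dust particles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.morphology import local_maxima, reconstruction

__all__ = [
    "ImageFrame",
    "SpotSet",
    "denoise",
    "subtract_background",
    "transform_intensity",
    "select_maxima",
    "detect_both",
    "detect_spots",
    "qc_filter",
    "DEFAULT_DENOISE_SIGMA",
    "DEFAULT_THRESHOLD_MULTIPLIER",
]

Channel = Literal["capture", "detection"]

DEFAULT_DENOISE_SIGMA = 0.8
DEFAULT_THRESHOLD_MULTIPLIER = 1.2
QC_MAX_OFFSET_PX = 75.0
# structuring element for the spot-relief estimate behind the default h;
# must be much wider than the PSF so single-molecule peaks are fully removed
RELIEF_OPENING_SIZE = (15, 15)


@dataclass(frozen=True)
class ImageFrame:
    """One stitched two-channel field of view.

    ``pixels`` is a (height, width) 16-bit grid; width must be even, the left
    half being the capture channel and the right half the detection channel.
    """

    pixels: np.ndarray
    fov_id: str = "fov_0"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if px.shape[1] % 2 != 0:
            raise ValueError("stitched frame width must be even (two half-channels)")
        if np.issubdtype(px.dtype, np.signedinteger) and px.min() < 0:
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def half_width(self) -> int:
        return self.pixels.shape[1] // 2

    def half(self, channel: Channel) -> np.ndarray:
        """View of one channel's half-image (left = capture, right = detection)."""
        if channel == "capture":
            return self.pixels[:, : self.half_width]
        if channel == "detection":
            return self.pixels[:, self.half_width :]
        raise ValueError(f"unknown channel {channel!r}")


@dataclass(frozen=True)
class SpotSet:
    """Detected spots for one channel of one FOV, in half-image coordinates."""

    fov_id: str
    channel: Channel
    xy: np.ndarray  # (n, 2) of (x = column, y = row), 0-based pixel centers
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))
    half_frame: bool = True

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        inten = np.asarray(self.intensity, dtype=float).ravel()
        if inten.size == 0:
            inten = np.zeros(len(xy))
        if inten.size != len(xy):
            raise ValueError("intensity length must match number of spots")
        object.__setattr__(self, "xy", xy)
        object.__setattr__(self, "intensity", inten)

    def __len__(self) -> int:
        return len(self.xy)


def denoise(frame: ImageFrame | np.ndarray, sigma: float = DEFAULT_DENOISE_SIGMA) -> np.ndarray:
    """Gaussian-filter a frame (default kernel sigma 0.8 px); input unmodified."""
    pixels = frame.pixels if isinstance(frame, ImageFrame) else np.asarray(frame)
    if pixels.size == 0:
        raise ValueError("cannot denoise an empty frame")
    return ndimage.gaussian_filter(pixels.astype(float), sigma=sigma)


def subtract_background(smoothed: np.ndarray, h: float | None = None) -> np.ndarray:
    """Remove smooth illumination background by morphological reconstruction.

    The seed ``smoothed − h`` is dilated under the mask ``smoothed``; the
    reconstruction recovers the slowly varying background but cannot climb
    peaks more prominent than ``h``, so ``smoothed − background`` isolates
    spots (heights capped at ``h``). The default ``h`` is 0.8 of the maximum
    local spot relief — the smoothed image minus its grey opening with a
    structuring element much wider than the PSF, which passes smooth
    illumination gradients through untouched — so genuine spots keep their
    full prominence while the threshold statistics stay spot-dominated.

    The result is non-negative everywhere (reconstruction never exceeds its
    mask). A bright smooth region near the illumination maximum can retain a
    residual dome of height up to ``h``; detection may report its regional
    maximum as one extra spot.
    """
    img = np.asarray(smoothed, dtype=float)
    if h is None:
        relief = img - ndimage.grey_opening(img, size=RELIEF_OPENING_SIZE)
        h = 0.8 * float(relief.max())
    if h == 0.0:
        return np.zeros_like(img)  # flat image: background is the image itself
    background = reconstruction(img - h, img, method="dilation")
    out = img - background
    return np.clip(out, 0.0, None)


def transform_intensity(subtracted: np.ndarray, scale: float | None = None) -> np.ndarray:
    """Map intensities through ``asinh(v / s)``, a strictly monotone compressor.

    The scale ``s`` defaults to the 99.9th percentile of the input, floored
    at one count, so only the extreme bright tail is compressed and the
    threshold statistics stay dominated by real spot structure.
    """
    img = np.asarray(subtracted, dtype=float)
    if scale is None:
        scale = max(float(np.percentile(img, 99.9)), 1.0)
    if scale <= 0:
        raise ValueError("asinh scale must be positive")
    return np.arcsinh(img / scale)


def select_maxima(
    transformed: np.ndarray,
    threshold_multiplier: float = DEFAULT_THRESHOLD_MULTIPLIER,
) -> tuple[np.ndarray, np.ndarray]:
    """Thresholded 8-connected local maxima of a transformed half-image.

    Keeps maxima whose value is at least ``median + multiplier · std`` of the
    whole transformed half-image. Plateaus collapse to their centroid. Returns
    ``(xy, intensities)``. A zero-contrast image yields no spots.
    """
    img = np.asarray(transformed, dtype=float)
    std = float(img.std())
    if std == 0.0:
        return np.empty((0, 2)), np.empty(0)
    threshold = float(np.median(img)) + threshold_multiplier * std

    peaks = local_maxima(img, connectivity=2)
    labels, n = ndimage.label(peaks, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.empty((0, 2)), np.empty(0)
    idx = np.arange(1, n + 1)
    values = np.array(ndimage.maximum(img, labels, idx))
    keep = values >= threshold
    if not keep.any():
        return np.empty((0, 2)), np.empty(0)
    centroids = np.array(ndimage.center_of_mass(peaks, labels, idx[keep]))
    xy = centroids[:, ::-1]  # (row, col) -> (x, y)
    return xy, values[keep]


def detect_both(
    frame: ImageFrame,
    *,
    sigma: float = DEFAULT_DENOISE_SIGMA,
    h: float | None = None,
    asinh_scale: float | None = None,
    threshold_multiplier: float = DEFAULT_THRESHOLD_MULTIPLIER,
) -> tuple[SpotSet, SpotSet]:
    """Run the detection recipe on a stitched frame; split spots by half.

    Returns ``(capture, detection)`` SpotSets, each in its own half-image
    coordinate frame. A maximum at exactly the channel boundary column is
    assigned to the detection (right) half. The input frame is never mutated;
    an all-constant image yields empty SpotSets.
    """
    smoothed = denoise(frame, sigma=sigma)
    subtracted = subtract_background(smoothed, h=h)
    transformed = transform_intensity(subtracted, scale=asinh_scale)
    xy, intensities = select_maxima(transformed, threshold_multiplier)

    hw = frame.half_width
    left = xy[:, 0] < hw
    cap = SpotSet(fov_id=frame.fov_id, channel="capture",
                  xy=xy[left], intensity=intensities[left])
    det_xy = xy[~left].copy()
    det_xy[:, 0] -= hw
    det = SpotSet(fov_id=frame.fov_id, channel="detection",
                  xy=det_xy, intensity=intensities[~left])
    return cap, det


def detect_spots(
    frame: ImageFrame,
    channel: Channel,
    **kwargs,
) -> SpotSet:
    """One channel's spots from the stitched-frame recipe (see detect_both)."""
    cap, det = detect_both(frame, **kwargs)
    if channel == "capture":
        return cap
    if channel == "detection":
        return det
    raise ValueError(f"unknown channel {channel!r}")


def qc_filter(
    spots: SpotSet,
    image_height_px: int,
    max_offset_px: float = QC_MAX_OFFSET_PX,
) -> bool:
    """Keep a FOV iff its capture spots are vertically well-distributed.

    Returns True (keep) when ``|mean(y) − height/2| <= max_offset_px``; an
    empty SpotSet is discarded.
    """
    if len(spots) == 0:
        return False
    mean_y = float(spots.xy[:, 1].mean())
    return abs(mean_y - image_height_px / 2.0) <= max_offset_px
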