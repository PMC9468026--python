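"""Inter-channel affine registration from fiducial-bead frames.

The two halves of a stitched two-color frame are imaged through different
optical paths, so detection-channel coordinates are related to capture-channel
coordinates by a small affine map (near-identity rotation/scale plus a
translation of a few pixels). The map is estimated from multi-color fiducial
beads visible in both channels: bead spots are paired across channels by
mutual nearest neighbors, a least-squares affine is fitted per frame, and the
per-frame matrices are averaged element-wise into the final transform.

Coordinates are continuous, 0-based, ``(x = column, y = row)``, origin at the
top-left pixel center, expressed in the half-image frame of each channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "AffineTransform2D",
    "DegenerateGeometryError",
    "match_beads",
    "estimate_affine",
    "average_transforms",
    "apply_transform",
]


class DegenerateGeometryError(ValueError):
    """Raised when bead geometry cannot determine an affine map."""


@dataclass(frozen=True)
class AffineTransform2D:
    """A 2-D affine map in 3x3 homogeneous form, last row ``[0, 0, 1]``.

    Maps column vectors ``[x, y, 1]^T``; must be invertible so coordinates can
    be moved between channel frames in either direction.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"affine matrix must be 3x3, got {m.shape}")
        if not np.allclose(m[2], [0.0, 0.0, 1.0], atol=1e-12):
            raise ValueError("last row of an affine matrix must be [0, 0, 1]")
        if abs(np.linalg.det(m[:2, :2])) < 1e-12:
            raise DegenerateGeometryError("affine matrix is singular")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.eye(3))

    @classmethod
    def from_translation(cls, tx: float, ty: float) -> "AffineTransform2D":
        m = np.eye(3)
        m[0, 2] = tx
        m[1, 2] = ty
        return cls(m)

    @classmethod
    def from_params(
        cls,
        *,
        rotation_deg: float = 0.0,
        scale: float = 1.0,
        tx: float = 0.0,
        ty: float = 0.0,
    ) -> "AffineTransform2D":
        th = np.deg2rad(rotation_deg)
        m = np.eye(3)
        m[:2, :2] = scale * np.array(
            [[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]
        )
        m[0, 2], m[1, 2] = tx, ty
        return cls(m)

    def inverse(self) -> "AffineTransform2D":
        return AffineTransform2D(np.linalg.inv(self.matrix))

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return apply_transform(self, points)


def match_beads(
    capture_xy: np.ndarray,
    detection_xy: np.ndarray,
    max_distance_px: float = 5.0,
    leaf_size: int = 30,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair bead coordinates across channels by mutual nearest neighbor.

    Parameters
    ----------
    capture_xy, detection_xy : (n, 2) arrays
        Bead spot coordinates in each channel's half-image frame.
    max_distance_px : float
        Gate on the pairing distance; candidate pairs further apart are
        dropped.  Keeps a bead missing from one channel from stealing a
        neighbor's partner.
    leaf_size : int
        KD-tree leaf size; an accelerator only, never changes the pairing.

    Returns
    -------
    (cap, det) : two (m, 2) arrays of matched coordinates, m >= 3.

    Raises
    ------
    DegenerateGeometryError
        If fewer than 3 mutual pairs survive the distance gate.
    """
    cap = np.atleast_2d(np.asarray(capture_xy, dtype=float))
    det = np.atleast_2d(np.asarray(detection_xy, dtype=float))
    if cap.size == 0 or det.size == 0:
        raise DegenerateGeometryError("empty bead coordinate set")
    if max_distance_px <= 0:
        raise ValueError("max_distance_px must be positive")

    cap_tree = cKDTree(cap, leafsize=leaf_size)
    det_tree = cKDTree(det, leafsize=leaf_size)
    d_cd, nn_cd = det_tree.query(cap)  # for each capture bead: nearest detection
    _, nn_dc = cap_tree.query(det)  # for each detection bead: nearest capture

    pairs = [
        (i, j)
        for i, (j, d) in enumerate(zip(nn_cd, d_cd))
        if nn_dc[j] == i and d <= max_distance_px
    ]
    if len(pairs) < 3:
        raise DegenerateGeometryError(
            f"only {len(pairs)} mutual bead pairs within {max_distance_px} px; "
            "need at least 3"
        )
    idx_c, idx_d = map(np.asarray, zip(*pairs))
    return cap[idx_c], det[idx_d]


def estimate_affine(src: np.ndarray, dst: np.ndarray) -> AffineTransform2D:
    """Least-squares affine ``T`` with ``dst ≈ T · src``.

    Solves ``min_T Σ‖T·src_i − dst_i‖²`` over homogeneous coordinates; exact
    for three non-collinear pairs, the pseudo-inverse solution for more.
    """
    src = np.atleast_2d(np.asarray(src, dtype=float))
    dst = np.atleast_2d(np.asarray(dst, dtype=float))
    if src.shape != dst.shape or src.shape[1] != 2:
        raise ValueError("src and dst must be matching (n, 2) arrays")
    n = src.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 point pairs, got {n}")

    a = np.column_stack([src, np.ones(n)])  # (n, 3) design [x, y, 1]
    if np.linalg.matrix_rank(a, tol=1e-9 * max(1.0, np.abs(a).max())) < 3:
        raise DegenerateGeometryError("point pairs are collinear (rank-deficient)")
    sol, *_ = np.linalg.lstsq(a, dst, rcond=None)  # (3, 2): columns [x', y']
    m = np.eye(3)
    m[:2, :] = sol.T
    return AffineTransform2D(m)


def average_transforms(
    transforms: Sequence[AffineTransform2D],
) -> AffineTransform2D:
    """Element-wise mean of per-frame transform matrices."""
    if len(transforms) == 0:
        raise ValueError("cannot average an empty list of transforms")
    stack = np.stack([t.matrix for t in transforms])
    return AffineTransform2D(stack.mean(axis=0))


def apply_transform(t: AffineTransform2D, points: np.ndarray) -> np.ndarray:
    """Apply ``t`` to an (n, 2) array of ``(x, y)`` points; input unmodified."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        return pts.reshape(0, 2).copy()
    if pts.shape[1] != 2:
        raise ValueError("points must have shape (n, 2)")
    homog = np.column_stack([pts, np.ones(len(pts))])
    out = homog @ t.matrix.T
    return out[:, :2]
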