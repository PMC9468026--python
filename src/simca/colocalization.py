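"""Colocalization counting and normalized per-FOV statistics.

A detection-antibody spot is a true binding event only if, after mapping its
coordinates into the capture frame through the inter-channel affine
transform, it lies within 1.5 px of a capture-antibody spot. Pairing is
one-to-one (single-sandwich chemistry): candidate pairs within the radius are
sorted by distance and accepted greedily while both members are unassigned,
so ``coloc_count <= min(cab_count, dab_count)`` always holds.

Two normalizations divide by the per-FOV capture count to cancel
heterogeneous capture-antibody surface loading:

    normalized_coloc  = coloc_count / cab_count
    normalized_single = dab_count   / cab_count
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .detection import SpotSet
from .registration import AffineTransform2D, apply_transform

__all__ = [
    "FovCounts",
    "DEFAULT_COLOC_RADIUS_PX",
    "colocalize",
    "normalize",
    "aggregate_counts",
]

DEFAULT_COLOC_RADIUS_PX = 1.5


@dataclass(frozen=True)
class FovCounts:
    """Per-FOV spot counts and the derived normalized statistics.

    ``normalized_coloc`` lies in [0, 1] when ``cab_count > 0``: 1 is the
    theoretical maximum binding (every capture antibody occupied), 0 the
    minimum. A FOV with ``cab_count == 0`` is flagged invalid and excluded
    from aggregation rather than raising.
    """

    fov_id: str
    cab_count: int
    dab_count: int
    coloc_count: int
    normalized_coloc: float = np.nan
    normalized_single: float = np.nan
    concentration_pm: float | None = None
    matrix_label: str | None = None
    coverslip: str | None = None
    valid: bool = True

    def __post_init__(self) -> None:
        if min(self.cab_count, self.dab_count, self.coloc_count) < 0:
            raise ValueError("counts must be non-negative")
        if self.coloc_count > min(self.cab_count, self.dab_count):
            raise ValueError("coloc_count cannot exceed min(cab_count, dab_count)")


def colocalize(
    cab: SpotSet,
    dab: SpotSet,
    transform: AffineTransform2D,
    radius_px: float = DEFAULT_COLOC_RADIUS_PX,
) -> tuple[FovCounts, list[tuple[int, int]]]:
    """Count one-to-one colocalized pairs at the Euclidean-distance criterion.

    ``transform`` maps detection-frame coordinates into the capture frame.
    Candidate pairs within ``radius_px`` are sorted by (distance, capture
    index, detection index) and accepted greedily while both spots are
    unassigned. Returns the per-FOV counts (ratios not yet filled; see
    :func:`normalize`) and the accepted ``(cab_index, dab_index)`` pairs.
    """
    if radius_px <= 0:
        raise ValueError("radius_px must be positive")
    if cab.fov_id != dab.fov_id:
        raise ValueError("capture and detection SpotSets must share a FOV")

    pairs: list[tuple[int, int]] = []
    if len(cab) > 0 and len(dab) > 0:
        dab_in_cap = apply_transform(transform, dab.xy)
        tree = cKDTree(cab.xy)
        candidates = []
        for j, p in enumerate(dab_in_cap):
            for i in tree.query_ball_point(p, radius_px):
                d = float(np.linalg.norm(cab.xy[i] - p))
                candidates.append((d, i, j))
        candidates.sort()
        used_c: set[int] = set()
        used_d: set[int] = set()
        for _, i, j in candidates:
            if i not in used_c and j not in used_d:
                used_c.add(i)
                used_d.add(j)
                pairs.append((i, j))

    counts = FovCounts(
        fov_id=cab.fov_id,
        cab_count=len(cab),
        dab_count=len(dab),
        coloc_count=len(pairs),
    )
    return counts, pairs


def normalize(counts: FovCounts) -> FovCounts:
    """Fill the capture-normalized ratios; flag FOVs with no capture spots."""
    if counts.cab_count == 0:
        return replace(counts, valid=False,
                       normalized_coloc=np.nan, normalized_single=np.nan)
    return replace(
        counts,
        normalized_coloc=counts.coloc_count / counts.cab_count,
        normalized_single=counts.dab_count / counts.cab_count,
    )


_STATS = ["cab_count", "dab_count", "coloc_count",
          "normalized_coloc", "normalized_single"]


def counts_to_frame(fovs: Sequence[FovCounts]) -> pd.DataFrame:
    """Tabulate FovCounts records (one row per FOV)."""
    return pd.DataFrame([vars(f) for f in fovs])


def aggregate_counts(fovs: Sequence[FovCounts]) -> pd.DataFrame:
    """Mean, sample std (n−1) and CV of each statistic per condition.

    Groups by concentration and coverslip where labeled; invalid FOVs
    (no capture spots) are excluded. CV = std/mean quantifies the
    across-FOV consistency each statistic achieves.
    """
    df = counts_to_frame(fovs)
    df = df[df["valid"]]
    if len(df) < 2:
        raise ValueError("need at least 2 valid FOVs to aggregate")
    group_cols = [
        c for c in ("concentration_pm", "matrix_label", "coverslip")
        if df[c].notna().any()
    ]
    grouped = df.groupby(group_cols, dropna=False) if group_cols else [((), df)]

    rows = []
    for key, g in grouped:
        row: dict = dict(zip(group_cols, np.atleast_1d(key)))
        row["n_fov"] = len(g)
        for stat in _STATS:
            mean = g[stat].mean()
            std = g[stat].std(ddof=1)
            row[f"{stat}_mean"] = mean
            row[f"{stat}_std"] = std
            row[f"{stat}_cv"] = std / mean if mean != 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
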