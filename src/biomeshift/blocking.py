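"""Spatial blocking and leakage-safe cross-validation folds.

Observation points are projected to a world sinusoidal equal-area
projection on the authalic sphere (origin 0E/0N) and binned into
block_size_km x block_size_km tiles; folds are assigned per block, never
per point, so that nearby (spatially autocorrelated) points can never sit
on both sides of a train/test split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import ObservationTable

__all__ = [
    "AUTHALIC_RADIUS_KM",
    "BlockAssignment",
    "FoldAssignment",
    "sinusoidal_xy",
    "assign_blocks",
    "make_spatial_folds",
]

#: authalic Earth radius in km (sphere with the WGS84 ellipsoid's area)
AUTHALIC_RADIUS_KM = 6371.0072


def sinusoidal_xy(lon, lat, radius_km: float = AUTHALIC_RADIUS_KM):
    """World sinusoidal projection: x = R*lambda*cos(phi), y = R*phi (km)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any((lon < -180) | (lon > 180)) or np.any((lat < -90) | (lat > 90)):
        raise ValueError("coordinates outside [-180, 180] x [-90, 90]")
    lam = np.deg2rad(lon)
    phi = np.deg2rad(lat)
    return radius_km * lam * np.cos(phi), radius_km * phi


@dataclass
class BlockAssignment:
    """Per point: the (column, row) index of its metric block."""

    frame: pd.DataFrame  # point_id, block_x, block_y
    block_size_km: float

    @property
    def block_ids(self) -> pd.Series:
        return pd.Series(
            list(zip(self.frame["block_x"], self.frame["block_y"])),
            index=self.frame.index,
        )

    @property
    def n_blocks(self) -> int:
        return self.frame[["block_x", "block_y"]].drop_duplicates().shape[0]

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class FoldAssignment:
    """Per point: a fold in {1..k}; all points of a block share a fold."""

    fold: np.ndarray  # aligned with the originating observation order
    point_id: np.ndarray
    k: int
    repeat_index: int
    seed: int

    def __post_init__(self) -> None:
        present = np.unique(self.fold)
        if len(present) and (present.min() < 1 or present.max() > self.k):
            raise ValueError("fold labels must lie in 1..k")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "point_id": self.point_id,
                "fold": self.fold,
                "repeat": self.repeat_index,
            }
        )


def assign_blocks(
    points: ObservationTable, block_size_km: float = 100.0
) -> BlockAssignment:
    """Bin points into block_size_km tiles of the sinusoidal metric grid.

    Block indices are floor(x/s), floor(y/s); two points ~45 km apart on
    the equator share a block at the default 100 km size, points ~133 km
    apart do not.
    """
    if block_size_km <= 0:
        raise ValueError("block_size_km must be positive")
    x, y = sinusoidal_xy(points.lon, points.lat)
    bx = np.floor(x / block_size_km).astype(int)
    by = np.floor(y / block_size_km).astype(int)
    frame = pd.DataFrame(
        {"point_id": points.frame["point_id"].to_numpy(), "block_x": bx, "block_y": by}
    )
    return BlockAssignment(frame=frame, block_size_km=block_size_km)


def make_spatial_folds(
    blocks: BlockAssignment, k: int = 5, repeat_index: int = 0, seed: int = 0
) -> FoldAssignment:
    """Deal blocks round-robin into k folds after a seeded permutation.

    All points of a block inherit the block's fold; fold sizes in blocks
    differ by at most one. Deterministic in (seed, repeat_index).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    uniq = sorted(set(zip(blocks.frame["block_x"], blocks.frame["block_y"])))
    if len(uniq) < k:
        raise ValueError(
            f"cannot build {k} spatial folds from only {len(uniq)} distinct blocks"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, repeat_index]))
    perm = rng.permutation(len(uniq))
    fold_of_block = {uniq[j]: (i % k) + 1 for i, j in enumerate(perm)}
    fold = np.array(
        [
            fold_of_block[(bx, by)]
            for bx, by in zip(blocks.frame["block_x"], blocks.frame["block_y"])
        ],
        dtype=int,
    )
    return FoldAssignment(
        fold=fold,
        point_id=blocks.frame["point_id"].to_numpy(),
        k=k,
        repeat_index=repeat_index,
        seed=seed,
    )
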