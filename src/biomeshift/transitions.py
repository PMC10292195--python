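"""Confidence-filtered biome transition mapping and equal-area accounting.

Transitions between a current and a future hard-class map are counted only
where the margin of victory clears a confidence threshold (>= 50
percentage points by default, on both epochs' maps). Pixel areas are
computed analytically per latitude band on the authalic sphere with the
exact spherical-zone formula — the same area totals an equal-area
reprojection would give, without resampling artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blocking import AUTHALIC_RADIUS_KM
from .maps import HardClassMap
from .synthetic import GridSpec

__all__ = [
    "PixelAreaGrid",
    "ChangeMap",
    "TransitionTable",
    "pixel_areas",
    "detect_transitions",
    "scenario_agreement",
    "transition_areas",
]

FILTER_MODES = ("both", "current", "future")


@dataclass
class PixelAreaGrid:
    """Per-latitude-band pixel area in km^2 (constant along a row)."""

    grid: GridSpec
    row_areas: np.ndarray  # (n_rows,)

    def as_grid(self) -> np.ndarray:
        return np.repeat(self.row_areas[:, None], self.grid.n_cols, axis=1)

    def total(self) -> float:
        return float(self.row_areas.sum() * self.grid.n_cols)


def pixel_areas(grid: GridSpec, radius_km: float = AUTHALIC_RADIUS_KM) -> PixelAreaGrid:
    """Exact spherical-zone pixel areas: R^2 * dlambda * (sin top - sin bottom)."""
    lat_top = grid.lat_max - np.arange(grid.n_rows) * grid.cell_size
    lat_bottom = lat_top - grid.cell_size
    if np.any(lat_bottom < -90.0 - 1e-9) or np.any(lat_top > 90.0 + 1e-9):
        raise ValueError("grid latitude bounds leave [-90, 90]")
    dlam = np.deg2rad(grid.cell_size)
    areas = radius_km**2 * dlam * (np.sin(np.deg2rad(lat_top)) - np.sin(np.deg2rad(lat_bottom)))
    return PixelAreaGrid(grid=grid, row_areas=areas)


@dataclass
class ChangeMap:
    """Per-pixel transition state between two co-registered hard maps."""

    grid: GridSpec
    class_list: list
    from_classes: np.ndarray
    to_classes: np.ndarray
    changed: np.ndarray  # bool: hard class differs
    confident: np.ndarray  # bool: passes the MoV filter
    mask: np.ndarray
    filter_threshold: float
    filter_mode: str

    @property
    def confident_changed(self) -> np.ndarray:
        return self.changed & self.confident & ~self.mask


def detect_transitions(
    current: tuple[HardClassMap, np.ndarray],
    future: tuple[HardClassMap, np.ndarray],
    threshold: float = 50.0,
    filter_mode: str = "both",
) -> ChangeMap:
    """Flag pixels whose hard class changes with sufficient confidence.

    ``current`` and ``future`` are (hard map, MoV layer) pairs. A pixel is
    *changed* when the hard classes differ and *confident* when the margin
    of victory is >= threshold (inclusive) on both maps (mode "both", the
    conservative default) or on only the named epoch's map. Pixels failing
    the filter are excluded from all downstream tallies.
    """
    cur_map, cur_mov = current
    fut_map, fut_mov = future
    if cur_map.grid != fut_map.grid:
        raise ValueError("hard maps are not co-registered (grid mismatch)")
    if list(cur_map.class_list) != list(fut_map.class_list):
        raise ValueError("hard maps use different class legends")
    if filter_mode not in FILTER_MODES:
        raise ValueError(f"filter_mode must be one of {FILTER_MODES}")
    mask = cur_map.mask | fut_map.mask
    changed = (cur_map.classes != fut_map.classes) & ~mask
    with np.errstate(invalid="ignore"):
        ok_cur = cur_mov >= threshold
        ok_fut = fut_mov >= threshold
    if filter_mode == "both":
        confident = ok_cur & ok_fut
    elif filter_mode == "current":
        confident = ok_cur
    else:
        confident = ok_fut
    confident = confident & ~mask
    return ChangeMap(
        grid=cur_map.grid,
        class_list=list(cur_map.class_list),
        from_classes=cur_map.classes.copy(),
        to_classes=fut_map.classes.copy(),
        changed=changed,
        confident=confident,
        mask=mask,
        filter_threshold=threshold,
        filter_mode=filter_mode,
    )


def scenario_agreement(changes: list[ChangeMap]) -> np.ndarray:
    """Per-pixel count of scenarios flagging a confident change (0..S)."""
    if not changes:
        raise ValueError("need at least one change map")
    grid = changes[0].grid
    for ch in changes[1:]:
        if ch.grid != grid:
            raise ValueError("change maps are not co-registered")
    return np.sum([ch.confident_changed for ch in changes], axis=0).astype(int)


@dataclass
class TransitionTable:
    """from-class x to-class area matrix in km^2 (diagonal zero)."""

    class_list: list
    areas_km2: pd.DataFrame  # index = from, columns = to

    @property
    def grand_total(self) -> float:
        return float(self.areas_km2.to_numpy().sum())

    def to_long(self) -> pd.DataFrame:
        long = (
            self.areas_km2.rename_axis("from_class")
            .reset_index()
            .melt(id_vars="from_class", var_name="to_class", value_name="km2")
        )
        return long[long["km2"] > 0].reset_index(drop=True)


def transition_areas(change: ChangeMap, areas: PixelAreaGrid) -> TransitionTable:
    """Tally the equal-area km^2 of each confident from->to class pair."""
    if areas.grid != change.grid:
        raise ValueError("area grid does not match the change map")
    K = len(change.class_list)
    table = np.zeros((K, K))
    sel = change.confident_changed
    if sel.any():
        area_grid = areas.as_grid()
        np.add.at(
            table,
            (change.from_classes[sel], change.to_classes[sel]),
            area_grid[sel],
        )
    frame = pd.DataFrame(table, index=list(change.class_list), columns=list(change.class_list))
    return TransitionTable(class_list=list(change.class_list), areas_km2=frame)
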