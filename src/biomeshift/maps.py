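"""Per-pixel map products: hard classes, margin of victory, legend
aggregation.

Probabilities are stored and reported in percent (0-100, summing to 100
per unmasked pixel); the margin of victory (MoV) — the difference between
the highest and second-highest class probability in a pixel — ranges from
0 (top two classes tie, maximal confusion) to 100 (one-hot certainty) and
is the package's per-pixel confidence metric.

The module also carries the 20-class BIOME 6000 -> 6-class IUCN terrestrial
biome (T1-T6) translation scheme; the intensive land-use biome T7 has no
natural-vegetation source class and is excluded by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import GridSpec

__all__ = [
    "ProbabilityCube",
    "TranslationScheme",
    "UncertaintyLayers",
    "HardClassMap",
    "margin_of_victory",
    "hard_classify",
    "translate_probabilities",
    "BIOME6000_CLASSES",
    "IUCN_CLASSES",
    "BIOME6000_TO_IUCN",
]

_SUM_TOL = 1e-6


@dataclass
class ProbabilityCube:
    """Per-pixel per-class probabilities in percent on one grid."""

    grid: GridSpec
    class_list: list
    values: np.ndarray  # (K, H, W), NaN on masked pixels
    mask: np.ndarray

    def __post_init__(self) -> None:
        K = len(self.class_list)
        if self.values.shape != (K,) + self.grid.shape:
            raise ValueError("values must be shaped (K, n_rows, n_cols)")
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask does not match the grid")
        valid = self.values[:, ~self.mask]
        if valid.size:
            if np.nanmin(valid) < -_SUM_TOL or np.nanmax(valid) > 100 + _SUM_TOL:
                raise ValueError("probabilities must lie in [0, 100] percent")
            sums = valid.sum(axis=0)
            if np.any(np.abs(sums - 100.0) > 1e-4):
                raise ValueError("unmasked pixels must sum to 100 percent")

    @property
    def K(self) -> int:
        return len(self.class_list)


@dataclass
class HardClassMap:
    """Per-pixel argmax class index into class_list; -1 = nodata."""

    grid: GridSpec
    class_list: list
    classes: np.ndarray  # int (H, W)
    mask: np.ndarray


@dataclass
class UncertaintyLayers:
    """MoV (percentage points) and per-class base-learner SD (percent)."""

    mov: np.ndarray
    sd: np.ndarray | None = None


def margin_of_victory(cube: ProbabilityCube) -> np.ndarray:
    """Per-pixel first-minus-second highest class probability (0-100 pp).

    Masked pixels are NaN.
    """
    if cube.K < 2:
        raise ValueError("margin of victory needs at least two classes")
    vals = cube.values.reshape(cube.K, -1)
    out = np.full(vals.shape[1], np.nan)
    valid = ~cube.mask.ravel()
    v = vals[:, valid]
    part = np.partition(v, cube.K - 2, axis=0)
    out[valid] = part[-1] - part[-2]
    return out.reshape(cube.grid.shape)


def hard_classify(cube: ProbabilityCube) -> HardClassMap:
    """Per-pixel argmax class; ties break to the lowest legend index."""
    flat = cube.values.reshape(cube.K, -1)
    classes = np.full(flat.shape[1], -1, dtype=int)
    valid = ~cube.mask.ravel()
    classes[valid] = np.argmax(flat[:, valid], axis=0)
    return HardClassMap(
        grid=cube.grid,
        class_list=list(cube.class_list),
        classes=classes.reshape(cube.grid.shape),
        mask=cube.mask.copy(),
    )


@dataclass(frozen=True)
class TranslationScheme:
    """Total map from a source legend onto a coarser target legend."""

    mapping: dict
    target_list: tuple

    def __post_init__(self) -> None:
        extra = set(self.mapping.values()) - set(self.target_list)
        if extra:
            raise ValueError(f"mapped targets outside the target legend: {sorted(extra)}")

    def target_of(self, source):
        try:
            return self.mapping[source]
        except KeyError:
            raise KeyError(f"source class {source!r} absent from the translation scheme")


def translate_probabilities(
    cube: ProbabilityCube, scheme: TranslationScheme
) -> ProbabilityCube:
    """Aggregate class probabilities onto the scheme's target legend.

    The target probability is the sum of the mapped source probabilities;
    per-pixel mass is conserved exactly, so no renormalization happens.
    """
    for src in cube.class_list:
        scheme.target_of(src)  # raises naming the missing class
    targets = list(scheme.target_list)
    H, W = cube.grid.shape
    out = np.zeros((len(targets), H, W))
    for i, src in enumerate(cube.class_list):
        j = targets.index(scheme.mapping[src])
        out[j] += np.nan_to_num(cube.values[i], nan=0.0)
    out[:, cube.mask] = np.nan
    return ProbabilityCube(
        grid=cube.grid, class_list=targets, values=out, mask=cube.mask.copy()
    )


# ---------------------------------------------------------------------------
# BIOME 6000 -> IUCN terrestrial biome legend
# ---------------------------------------------------------------------------

IUCN_CLASSES = (
    "T1 - Tropical-subtropical forests biome",
    "T2 - Temperate-boreal forests and woodlands biome",
    "T3 - Shrublands and shrubby woodlands biome",
    "T4 - Savannas and grasslands biome",
    "T5 - Deserts and semi-deserts biome",
    "T6 - Polar/alpine (cryogenic) biome",
)

#: legend (row) order also fixes the canonical tie-break order
_BIOME6000_ROWS = (
    ("Tropical deciduous broadleaf forest and woodland", IUCN_CLASSES[0]),
    ("Tropical evergreen broadleaf forest", IUCN_CLASSES[0]),
    ("Tropical semi evergreen broadleaf forest", IUCN_CLASSES[0]),
    ("Cold deciduous forest", IUCN_CLASSES[1]),
    ("Cold evergreen needleleaf forest", IUCN_CLASSES[1]),
    ("Cool evergreen needleleaf forest", IUCN_CLASSES[1]),
    ("Cool mixed forest", IUCN_CLASSES[1]),
    ("Cool temperate rainforest", IUCN_CLASSES[1]),
    ("Temperate deciduous broadleaf forest", IUCN_CLASSES[1]),
    ("Temperate sclerophyll woodland and shrubland", IUCN_CLASSES[1]),
    ("Temperate evergreen needleleaf open woodland", IUCN_CLASSES[2]),
    ("Warm temperate evergreen and mixed forest", IUCN_CLASSES[2]),
    ("Xerophytic woods scrub", IUCN_CLASSES[2]),
    ("Tropical savanna", IUCN_CLASSES[3]),
    ("Desert", IUCN_CLASSES[4]),
    ("Steppe", IUCN_CLASSES[4]),
    ("Erect dwarf shrub tundra", IUCN_CLASSES[5]),
    ("Graminoid and forb tundra", IUCN_CLASSES[5]),
    ("Low and high shrub tundra", IUCN_CLASSES[5]),
    ("Prostrate dwarf shrub tundra", IUCN_CLASSES[5]),
)

BIOME6000_CLASSES = tuple(src for src, _ in _BIOME6000_ROWS)

BIOME6000_TO_IUCN = TranslationScheme(
    mapping={src: tgt for src, tgt in _BIOME6000_ROWS},
    target_list=IUCN_CLASSES,
)
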