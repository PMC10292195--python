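"""Synthetic covariate rasters, biome labels and observation points.

Generates seeded inputs with the statistical structure the downstream
analysis assumes: smooth spatially autocorrelated covariate fields with a
latitudinal temperature trend, labels derived from two latent covariates by
a recorded nested-threshold rule with geometric class-prevalence decay,
spatially clustered (pollen-site-like) observation sampling with label
noise, and "future scenario" covariate stacks built by additive warming and
multiplicative precipitation scaling.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

import pandas as pd

__all__ = [
    "GridSpec",
    "CovariateStack",
    "ObservationTable",
    "ScenarioDelta",
    "LabelRule",
    "LabelRaster",
    "generate_covariates",
    "generate_true_labels",
    "sample_observations",
    "perturb_scenario",
    "extract_features",
    "standard_fixture",
]

LAYER_KINDS = ("temperature", "precipitation", "terrain")


@dataclass(frozen=True)
class GridSpec:
    """Regular geographic grid (EPSG:4326-style lon/lat on a sphere).

    Row 0 is the northernmost row, matching raster conventions; the cell
    centre of row r sits at ``lat_max - (r + 0.5) * cell_size``.
    """

    n_rows: int
    n_cols: int
    lon_min: float
    lat_min: float
    cell_size: float
    crs_tag: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not (-90.0 <= self.lat_min and self.lat_max <= 90.0):
            raise ValueError("latitude extent must stay within [-90, 90]")

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.n_rows * self.cell_size

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.n_cols * self.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_center(self, row, col):
        """Lon/lat of cell centres (vectorised)."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.lon_min + (col + 0.5) * self.cell_size
        lat = self.lat_max - (row + 0.5) * self.cell_size
        return lon, lat

    def rowcol(self, lon, lat):
        """Row/col indices of the cells containing the given coordinates."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_min) / self.cell_size).astype(int)
        row = np.floor((self.lat_max - lat) / self.cell_size).astype(int)
        # points exactly on the max edge belong to the last cell
        col = np.clip(col, 0, self.n_cols - 1)
        row = np.clip(row, 0, self.n_rows - 1)
        return row, col

    def contains(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon_min)
            & (lon <= self.lon_max)
            & (lat >= self.lat_min)
            & (lat <= self.lat_max)
        )

    def lat_centers(self) -> np.ndarray:
        rows = np.arange(self.n_rows)
        return self.lat_max - (rows + 0.5) * self.cell_size


@dataclass
class CovariateStack:
    """Named co-registered raster layers on one grid.

    ``mask`` is True where cells are excluded from the analysis; excluded
    cells carry NaN in every layer. ``kinds`` tags each layer as
    temperature / precipitation / terrain so that scenario perturbations
    know what to shift and what to scale.
    """

    grid: GridSpec
    layers: dict[str, np.ndarray]
    kinds: dict[str, str]
    mask: np.ndarray

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("a covariate stack needs at least one layer")
        for name, arr in self.layers.items():
            if arr.shape != self.grid.shape:
                raise ValueError(f"layer {name!r} does not match the grid shape")
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask does not match the grid shape")
        missing = set(self.layers) - set(self.kinds)
        if missing:
            raise ValueError(f"layers without a kind tag: {sorted(missing)}")

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def copy(self) -> "CovariateStack":
        return CovariateStack(
            grid=self.grid,
            layers={k: v.copy() for k, v in self.layers.items()},
            kinds=dict(self.kinds),
            mask=self.mask.copy(),
        )

    def feature_matrix(self, names: Sequence[str] | None = None):
        """(n_unmasked, n_layers) matrix plus the flat unmasked index."""
        names = list(names) if names is not None else self.layer_names
        for n in names:
            if n not in self.layers:
                raise KeyError(f"missing feature layer: {n!r}")
        valid = ~self.mask
        X = np.column_stack([self.layers[n][valid] for n in names])
        return X, np.flatnonzero(valid.ravel())


@dataclass
class ObservationTable:
    """Point observations: id, lon/lat and a class label from a legend."""

    frame: pd.DataFrame
    legend: list[str]

    REQUIRED = ("point_id", "lon", "lat", "label")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise ValueError(f"observation table misses column {col!r}")
        if self.frame["point_id"].duplicated().any():
            raise ValueError("point ids must be unique")
        bad = set(self.frame["label"]) - set(self.legend)
        if bad:
            raise ValueError(f"labels outside the legend: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def lon(self) -> np.ndarray:
        return self.frame["lon"].to_numpy(dtype=float)

    @property
    def lat(self) -> np.ndarray:
        return self.frame["lat"].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy()

    def label_codes(self) -> np.ndarray:
        """Labels as indices into the legend order."""
        cat = pd.Categorical(self.frame["label"], categories=self.legend)
        return np.asarray(cat.codes, dtype=int)


@dataclass(frozen=True)
class ScenarioDelta:
    """Climate-scenario perturbation: additive warming, multiplicative
    precipitation scaling (emulating RCP-style future covariate stacks)."""

    temperature_shift: float
    precipitation_scale: float
    scenario_tag: str

    def __post_init__(self) -> None:
        if self.precipitation_scale <= 0:
            raise ValueError("precipitation_scale must be positive")


# ---------------------------------------------------------------------------
# covariate fields
# ---------------------------------------------------------------------------

# per-kind affine placement of the standardized random field, roughly on the
# scale of degrees Celsius / mm / metres so the layers look like climate data
_KIND_PARAMS = {
    "temperature": dict(base=25.0, amplitude=6.0, lat_slope=-0.45),
    "precipitation": dict(base=1200.0, log_amplitude=0.7),
    "terrain": dict(base=400.0, amplitude=350.0),
}


def _smooth_field(rng: np.random.Generator, shape, corr_length: float) -> np.ndarray:
    """Standardized random field: white noise convolved with an isotropic
    Gaussian kernel of scale (corr_length - 1); corr_length = 1 is the
    identity kernel and returns the raw noise."""
    noise = rng.standard_normal(shape)
    if corr_length <= 1:
        return noise
    f = gaussian_filter(noise, sigma=corr_length - 1, mode="reflect")
    return (f - f.mean()) / f.std()


def generate_covariates(
    grid: GridSpec,
    layer_spec: Sequence[tuple[str, str]],
    corr_length: float = 6.0,
    seed: int = 0,
) -> CovariateStack:
    """Generate a stack of smooth random covariate fields.

    Temperature-kind layers carry a monotone north-south latitudinal
    gradient on top of the random field; precipitation-kind layers are
    log-normal (strictly positive, right-skewed); terrain layers are plain
    smooth fields. Identical arguments give bit-identical output.
    """
    if not layer_spec:
        raise ValueError("layer_spec must name at least one layer")
    names = [n for n, _ in layer_spec]
    if len(set(names)) != len(names):
        raise ValueError("duplicate layer names in layer_spec")
    if corr_length < 1:
        raise ValueError("corr_length must be >= 1")
    for name, kind in layer_spec:
        if kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {kind!r} for layer {name!r}")

    rng = np.random.default_rng(seed)
    lat = grid.lat_centers()[:, None] * np.ones((1, grid.n_cols))
    layers: dict[str, np.ndarray] = {}
    kinds: dict[str, str] = {}
    for name, kind in layer_spec:
        f = _smooth_field(rng, grid.shape, corr_length)
        p = _KIND_PARAMS[kind]
        if kind == "temperature":
            layers[name] = p["base"] + p["lat_slope"] * lat + p["amplitude"] * f
        elif kind == "precipitation":
            layers[name] = p["base"] * np.exp(p["log_amplitude"] * f)
        else:
            layers[name] = p["base"] + p["amplitude"] * f
        kinds[name] = kind
    mask = np.zeros(grid.shape, dtype=bool)
    return CovariateStack(grid=grid, layers=layers, kinds=kinds, mask=mask)


# ---------------------------------------------------------------------------
# label rule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabelRule:
    """Recorded nested-threshold rule mapping two latent layers to classes.

    ``steps`` carve classes off in sequence: step i assigns class
    ``class_id`` to every still-unassigned cell whose value in ``layer`` is
    <= ``threshold``; the final class takes the remainder. Prevalences
    follow a geometric decay set by the skew parameter at generation time.
    """

    latent_layers: tuple[str, str]
    steps: tuple[tuple[str, float, int], ...]  # (layer, threshold, class_id)
    remainder_class: int
    class_names: tuple[str, ...]

    def classify(self, stack: CovariateStack) -> np.ndarray:
        """Re-apply the rule to a stack; masked cells get -1."""
        out = np.full(stack.grid.shape, -1, dtype=int)
        unassigned = ~stack.mask
        for layer, thr, cid in self.steps:
            sel = unassigned & (stack.layers[layer] <= thr)
            out[sel] = cid
            unassigned &= ~sel
        out[unassigned] = self.remainder_class
        out[stack.mask] = -1
        return out


@dataclass
class LabelRaster:
    """Ground-truth class raster plus the rule that generated it."""

    grid: GridSpec
    classes: np.ndarray  # int, -1 on masked cells
    class_names: list[str]
    rule: LabelRule
    mask: np.ndarray

    def prevalences(self) -> np.ndarray:
        valid = self.classes[self.classes >= 0]
        counts = np.bincount(valid, minlength=len(self.class_names))
        return counts / counts.sum()


def generate_true_labels(
    stack: CovariateStack,
    K: int,
    rule_seed: int = 0,
    prevalence_skew: float = 1.0,
    latent_layers: tuple[str, str] | None = None,
) -> LabelRaster:
    """Deterministically label every unmasked cell with one of K classes.

    Classes are carved off by nested quantile thresholds alternating between
    two latent layers, with target prevalences proportional to
    ``prevalence_skew**(-i)`` (skew 1 = equal classes). The rule is returned
    so tests can re-derive the raster.
    """
    if K < 2:
        raise ValueError("need at least two classes")
    if prevalence_skew < 1:
        raise ValueError("prevalence_skew must be >= 1")
    if len(stack.layers) < 2:
        raise ValueError("stack must supply at least two layers")
    n_valid = int((~stack.mask).sum())
    if K > n_valid:
        raise ValueError(
            f"K = {K} exceeds the {n_valid} unmasked cells available for the rule"
        )
    if latent_layers is None:
        names = stack.layer_names
        latent_layers = (names[0], names[1])
    for n in latent_layers:
        if n not in stack.layers:
            raise KeyError(f"latent layer {n!r} not in stack")

    # geometric target prevalences, largest first
    w = prevalence_skew ** (-np.arange(K, dtype=float))
    target = w / w.sum()

    rng = np.random.default_rng(rule_seed)
    class_order = rng.permutation(K)  # which class id gets which prevalence

    unassigned = ~stack.mask
    out = np.full(stack.grid.shape, -1, dtype=int)
    steps: list[tuple[str, float, int]] = []
    remaining_mass = 1.0
    for i in range(K - 1):
        layer = latent_layers[i % 2]
        frac = target[i] / remaining_mass
        vals = stack.layers[layer][unassigned]
        thr = float(np.quantile(vals, frac))
        sel = unassigned & (stack.layers[layer] <= thr)
        cid = int(class_order[i])
        out[sel] = cid
        unassigned &= ~sel
        steps.append((layer, thr, cid))
        remaining_mass -= target[i]
    out[unassigned] = int(class_order[K - 1])
    out[stack.mask] = -1

    class_names = [f"B{j + 1:02d}" for j in range(K)]
    rule = LabelRule(
        latent_layers=tuple(latent_layers),
        steps=tuple(steps),
        remainder_class=int(class_order[K - 1]),
        class_names=tuple(class_names),
    )
    return LabelRaster(
        grid=stack.grid,
        classes=out,
        class_names=class_names,
        rule=rule,
        mask=stack.mask.copy(),
    )


# ---------------------------------------------------------------------------
# observation sampling
# ---------------------------------------------------------------------------


def sample_observations(
    labels: LabelRaster,
    n_points: int,
    n_clusters: int = 25,
    label_noise: float = 0.0,
    seed: int = 0,
    cluster_std: float = 3.0,
) -> ObservationTable:
    """Sample spatially clustered observation points from a label raster.

    A two-stage scheme mimics the clustered geography of real pollen-site
    compilations: cluster centres are drawn uniformly over unmasked cells,
    points scatter around their centre with Gaussian spread ``cluster_std``
    (in cells). Each point takes the raster class at its cell, flipped to a
    uniformly random *other* class with probability ``label_noise``.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if not (0.0 <= label_noise < 1.0):
        raise ValueError("label_noise must lie in [0, 1)")
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    valid_rows, valid_cols = np.nonzero(~labels.mask)
    if len(valid_rows) == 0:
        raise ValueError("no unmasked cells to sample from")
    if n_points > len(valid_rows):
        raise ValueError(
            f"n_points = {n_points} exceeds the {len(valid_rows)} unmasked cells"
        )

    rng = np.random.default_rng(seed)
    centre_idx = rng.integers(0, len(valid_rows), size=n_clusters)
    centres = np.column_stack([valid_rows[centre_idx], valid_cols[centre_idx]])
    assignment = rng.integers(0, n_clusters, size=n_points)

    rows = np.empty(n_points, dtype=int)
    cols = np.empty(n_points, dtype=int)
    for i in range(n_points):
        cr, cc = centres[assignment[i]]
        for _ in range(64):  # reject masked / out-of-grid draws
            r = int(round(cr + rng.normal(0.0, cluster_std)))
            c = int(round(cc + rng.normal(0.0, cluster_std)))
            if 0 <= r < labels.grid.n_rows and 0 <= c < labels.grid.n_cols and not labels.mask[r, c]:
                break
        else:  # fall back to the (unmasked) centre cell
            r, c = int(cr), int(cc)
        rows[i], cols[i] = r, c

    true_codes = labels.classes[rows, cols]
    codes = true_codes.copy()
    K = len(labels.class_names)
    flip = rng.random(n_points) < label_noise
    if flip.any():
        # uniform over the K-1 other classes
        offsets = rng.integers(1, K, size=int(flip.sum()))
        codes[flip] = (codes[flip] + offsets) % K

    lon, lat = labels.grid.cell_center(rows, cols)
    frame = pd.DataFrame(
        {
            "point_id": [f"p{i + 1:06d}" for i in range(n_points)],
            "lon": lon,
            "lat": lat,
            "label": [labels.class_names[c] for c in codes],
        }
    )
    return ObservationTable(frame=frame, legend=list(labels.class_names))


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


def perturb_scenario(stack: CovariateStack, delta: ScenarioDelta) -> CovariateStack:
    """Apply a scenario perturbation: shift temperature-kind layers, scale
    precipitation-kind layers, leave terrain, mask and grid untouched."""
    out = stack.copy()
    for name, kind in out.kinds.items():
        if kind == "temperature":
            out.layers[name] = out.layers[name] + delta.temperature_shift
        elif kind == "precipitation":
            out.layers[name] = out.layers[name] * delta.precipitation_scale
    for name in out.layers:
        out.layers[name][out.mask] = np.nan
    return out


def extract_features(stack: CovariateStack, obs: ObservationTable):
    """Spatial overlay: covariate matrix at the observation points.

    Returns (X, feature_names) with X rows aligned to the observation table.
    """
    inside = stack.grid.contains(obs.lon, obs.lat)
    if not inside.all():
        raise ValueError(f"{int((~inside).sum())} points fall outside the grid extent")
    rows, cols = stack.grid.rowcol(obs.lon, obs.lat)
    names = stack.layer_names
    X = np.column_stack([stack.layers[n][rows, cols] for n in names])
    if not np.isfinite(X).all():
        raise ValueError("observation points overlap masked / nodata cells")
    return X, names


# ---------------------------------------------------------------------------
# the standard study-conditions fixture
# ---------------------------------------------------------------------------

STANDARD_LAYER_SPEC: tuple[tuple[str, str], ...] = (
    ("bio01_mean_annual_temp", "temperature"),
    ("bio02_mean_diurnal_range", "temperature"),
    ("bio05_max_temp_warmest", "temperature"),
    ("tmin_coldest_month", "temperature"),
    ("annual_precipitation", "precipitation"),
    ("precip_wettest_quarter", "precipitation"),
    ("precip_driest_quarter", "precipitation"),
    ("elevation", "terrain"),
)


def standard_fixture(seed: int = 0) -> dict:
    """The package's standard synthetic study: 128x128 grid (0.25 deg cells),
    8 covariates, K = 6 classes with geometric prevalence decay (skew 3),
    2,500 clustered points with 10% label noise.

    Returns a dict with the stack, label raster, observations, the overlay
    matrix X / label codes y, the class legend and feature names.
    """
    grid = GridSpec(n_rows=128, n_cols=128, lon_min=-16.0, lat_min=-16.0, cell_size=0.25)
    stack = generate_covariates(grid, STANDARD_LAYER_SPEC, corr_length=6.0, seed=seed)
    labels = generate_true_labels(
        stack,
        K=6,
        rule_seed=seed + 1,
        prevalence_skew=3.0,
        latent_layers=("bio01_mean_annual_temp", "annual_precipitation"),
    )
    obs = sample_observations(
        labels,
        n_points=2500,
        n_clusters=60,
        label_noise=0.10,
        seed=seed + 2,
        cluster_std=3.0,
    )
    X, feature_names = extract_features(stack, obs)
    return {
        "grid": grid,
        "stack": stack,
        "labels": labels,
        "observations": obs,
        "X": X,
        "y": obs.label_codes(),
        "legend": list(labels.class_names),
        "feature_names": feature_names,
    }
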