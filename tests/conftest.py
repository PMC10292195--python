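import numpy as np
import pytest

from biomeshift import (
    GridSpec,
    HyperParams,
    ProbabilityCube,
    assign_blocks,
    extract_features,
    generate_covariates,
    generate_true_labels,
    sample_observations,
)
from biomeshift.synthetic import STANDARD_LAYER_SPEC


@pytest.fixture(scope="session")
def light_hp():
    """Small ensemble configuration for fast unit tests (the tuned defaults
    stay on HyperParams())."""
    return HyperParams(
        rf_trees=60,
        rf_min_node=5,
        rf_mtry=4,
        gbt_rounds=10,
        glm_lambda=1e-4,
    )


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study: 48x48 grid, 4 classes, 700 clustered points."""
    grid = GridSpec(n_rows=48, n_cols=48, lon_min=-6.0, lat_min=-6.0, cell_size=0.25)
    stack = generate_covariates(grid, STANDARD_LAYER_SPEC, corr_length=5.0, seed=11)
    labels = generate_true_labels(
        stack,
        K=4,
        rule_seed=12,
        prevalence_skew=2.0,
        latent_layers=("bio01_mean_annual_temp", "annual_precipitation"),
    )
    obs = sample_observations(labels, n_points=700, n_clusters=25, label_noise=0.05, seed=13)
    X, feature_names = extract_features(stack, obs)
    blocks = assign_blocks(obs)
    return {
        "grid": grid,
        "stack": stack,
        "labels": labels,
        "observations": obs,
        "X": X,
        "y": obs.label_codes(),
        "feature_names": feature_names,
        "legend": list(labels.class_names),
        "blocks": blocks,
    }


def make_cube(values, mask=None, class_list=None):
    """Build a ProbabilityCube (percent) from a (K, H, W) array."""
    values = np.asarray(values, dtype=float)
    K, H, W = values.shape
    grid = GridSpec(n_rows=H, n_cols=W, lon_min=0.0, lat_min=0.0, cell_size=0.5)
    if mask is None:
        mask = np.zeros((H, W), dtype=bool)
    vals = values.copy()
    vals[:, mask] = np.nan
    return ProbabilityCube(
        grid=grid,
        class_list=list(class_list) if class_list is not None else [f"c{i}" for i in range(K)],
        values=vals,
        mask=mask,
    )
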