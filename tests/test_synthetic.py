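"""Synthetic generator contracts: determinism, autocorrelation control,
label-rule prevalences, clustered sampling and scenario perturbation."""

import numpy as np
import pytest

from biomeshift import (
    GridSpec,
    ScenarioDelta,
    generate_covariates,
    generate_true_labels,
    perturb_scenario,
    sample_observations,
)

GRID = GridSpec(n_rows=64, n_cols=64, lon_min=0.0, lat_min=0.0, cell_size=0.25)
SPEC2 = [("t1", "temperature"), ("p1", "precipitation")]


def lag1_autocorr(field):
    """Moran's-I-style lag-1 spatial correlation (independent oracle)."""
    f = field - field.mean()
    num = (f[:, :-1] * f[:, 1:]).mean() + (f[:-1, :] * f[1:, :]).mean()
    return num / (2 * f.var())


class TestGenerateCovariates:
    def test_same_seed_identical(self):
        a = generate_covariates(GRID, SPEC2, corr_length=4, seed=5)
        b = generate_covariates(GRID, SPEC2, corr_length=4, seed=5)
        for name in a.layer_names:
            np.testing.assert_array_equal(a.layers[name], b.layers[name])

    def test_different_seed_differs(self):
        a = generate_covariates(GRID, SPEC2, corr_length=4, seed=5)
        b = generate_covariates(GRID, SPEC2, corr_length=4, seed=6)
        assert not np.array_equal(a.layers["t1"], b.layers["t1"])

    def test_smoothing_raises_lag1_autocorrelation(self):
        rough = generate_covariates(GRID, [("e", "terrain")], corr_length=1, seed=3)
        smooth = generate_covariates(GRID, [("e", "terrain")], corr_length=16, seed=3)
        assert lag1_autocorr(smooth.layers["e"]) > lag1_autocorr(rough.layers["e"])

    def test_corr_length_one_is_identity_kernel(self):
        # width-1 kernel: output is the raw white-noise field
        out = generate_covariates(GRID, [("e", "terrain")], corr_length=1, seed=9)
        raw = np.random.default_rng(9).standard_normal(GRID.shape)
        np.testing.assert_allclose(out.layers["e"], 400.0 + 350.0 * raw)

    def test_temperature_has_north_south_gradient(self):
        big = GridSpec(n_rows=96, n_cols=32, lon_min=0.0, lat_min=-40.0, cell_size=0.5)
        stack = generate_covariates(big, [("t", "temperature")], corr_length=8, seed=1)
        row_means = stack.layers["t"].mean(axis=1)
        lat = big.lat_centers()
        assert np.corrcoef(row_means, lat)[0, 1] < -0.5

    @pytest.mark.parametrize(
        "spec,err",
        [
            ([], "at least one layer"),
            ([("a", "temperature"), ("a", "terrain")], "duplicate"),
            ([("a", "wind")], "unknown layer kind"),
        ],
    )
    def test_bad_layer_spec(self, spec, err):
        with pytest.raises(ValueError, match=err):
            generate_covariates(GRID, spec, corr_length=2, seed=0)


class TestGenerateTrueLabels:
    def setup_method(self):
        self.stack = generate_covariates(
            GridSpec(n_rows=128, n_cols=128, lon_min=0.0, lat_min=0.0, cell_size=0.2),
            SPEC2,
            corr_length=6,
            seed=2,
        )

    def test_skew_one_gives_equal_prevalences(self):
        lab = generate_true_labels(self.stack, K=4, rule_seed=0, prevalence_skew=1.0)
        prev = lab.prevalences()
        assert np.all(np.abs(prev - 0.25) < 0.02)

    def test_two_classes_split_at_median(self):
        lab = generate_true_labels(self.stack, K=2, rule_seed=0, prevalence_skew=1.0)
        prev = lab.prevalences()
        assert abs(prev[0] - 0.5) < 0.01

    def test_geometric_skew_three_k6_ratio_at_least_50(self):
        lab = generate_true_labels(self.stack, K=6, rule_seed=0, prevalence_skew=3.0)
        prev = lab.prevalences()
        assert prev.max() / prev.min() >= 50

    def test_rule_is_recorded_and_reproduces_raster(self):
        lab = generate_true_labels(self.stack, K=5, rule_seed=7, prevalence_skew=2.0)
        np.testing.assert_array_equal(lab.rule.classify(self.stack), lab.classes)

    def test_every_unmasked_cell_labelled(self):
        lab = generate_true_labels(self.stack, K=3, rule_seed=0, prevalence_skew=1.5)
        assert np.all(lab.classes[~lab.mask] >= 0)

    def test_k_too_large_errors(self):
        tiny = generate_covariates(
            GridSpec(n_rows=2, n_cols=2, lon_min=0, lat_min=0, cell_size=1.0),
            SPEC2, corr_length=1, seed=0,
        )
        with pytest.raises(ValueError, match="exceeds"):
            generate_true_labels(tiny, K=9, rule_seed=0)


class TestSampleObservations:
    def setup_method(self):
        stack = generate_covariates(GRID, SPEC2, corr_length=5, seed=4)
        self.labels = generate_true_labels(stack, K=4, rule_seed=1, prevalence_skew=1.5)

    def test_zero_noise_matches_raster(self):
        obs = sample_observations(self.labels, n_points=300, n_clusters=10,
                                  label_noise=0.0, seed=8)
        rows, cols = self.labels.grid.rowcol(obs.lon, obs.lat)
        true = self.labels.classes[rows, cols]
        np.testing.assert_array_equal(obs.label_codes(), true)

    def test_single_cluster_stays_local(self):
        obs = sample_observations(self.labels, n_points=200, n_clusters=1,
                                  label_noise=0.0, seed=8, cluster_std=2.0)
        rows, cols = self.labels.grid.rowcol(obs.lon, obs.lat)
        # all points within a few scatter SDs of the (single) cluster centre
        assert rows.std() < 4 * 2.0 and cols.std() < 4 * 2.0
        assert (rows.max() - rows.min()) < GRID.n_rows / 2

    def test_label_noise_rate_binomial(self):
        obs = sample_observations(self.labels, n_points=2000, n_clusters=30,
                                  label_noise=0.2, seed=8)
        rows, cols = self.labels.grid.rowcol(obs.lon, obs.lat)
        disagree = np.mean(obs.label_codes() != self.labels.classes[rows, cols])
        assert abs(disagree - 0.2) < 0.02

    def test_determinism(self):
        a = sample_observations(self.labels, n_points=100, n_clusters=5, seed=3)
        b = sample_observations(self.labels, n_points=100, n_clusters=5, seed=3)
        assert a.frame.equals(b.frame)

    def test_coordinates_inside_extent_and_ids_unique(self):
        obs = sample_observations(self.labels, n_points=500, n_clusters=20, seed=3)
        assert self.labels.grid.contains(obs.lon, obs.lat).all()
        assert obs.frame["point_id"].is_unique

    @pytest.mark.parametrize("kwargs", [
        {"n_points": 0}, {"n_points": 10, "label_noise": 1.0},
        {"n_points": 10, "n_clusters": 0},
    ])
    def test_bad_arguments(self, kwargs):
        with pytest.raises(ValueError):
            sample_observations(self.labels, **kwargs)


class TestPerturbScenario:
    def setup_method(self):
        self.stack = generate_covariates(
            GRID, SPEC2 + [("elev", "terrain")], corr_length=4, seed=6
        )
        self.stack.mask[:5] = True
        for name in self.stack.layers:
            self.stack.layers[name][self.stack.mask] = np.nan

    def test_identity_delta(self):
        out = perturb_scenario(self.stack, ScenarioDelta(0.0, 1.0, "base"))
        for name in out.layers:
            np.testing.assert_array_equal(out.layers[name], self.stack.layers[name])

    def test_temperature_shift_exact(self):
        out = perturb_scenario(self.stack, ScenarioDelta(5.0, 1.0, "warm"))
        valid = ~self.stack.mask
        np.testing.assert_allclose(
            out.layers["t1"][valid], self.stack.layers["t1"][valid] + 5.0
        )

    def test_precipitation_scales_mean_exactly(self):
        out = perturb_scenario(self.stack, ScenarioDelta(0.0, 0.8, "dry"))
        valid = ~self.stack.mask
        np.testing.assert_allclose(
            out.layers["p1"][valid].mean(), 0.8 * self.stack.layers["p1"][valid].mean()
        )

    def test_terrain_mask_and_grid_unchanged(self):
        out = perturb_scenario(self.stack, ScenarioDelta(3.0, 0.7, "x"))
        valid = ~self.stack.mask
        np.testing.assert_array_equal(out.layers["elev"][valid], self.stack.layers["elev"][valid])
        np.testing.assert_array_equal(out.mask, self.stack.mask)
        assert out.grid == self.stack.grid
        assert np.isnan(out.layers["t1"][self.stack.mask]).all()

    def test_nonpositive_precipitation_scale_rejected(self):
        with pytest.raises(ValueError):
            ScenarioDelta(0.0, 0.0, "bad")
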