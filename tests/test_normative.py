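"""Normative model: quantile curves, fold aggregation, deviation scoring."""

import numpy as np
import pytest

from dfcsubtype import (
    deviation_z,
    fit_aggregate_normative,
    fit_quantile_curves,
    score_cohort,
    score_heldout_controls,
)
from dfcsubtype.normative import DegenerateScaleError, QuantileCurveSet


def _gaussian_sample(n, seed, slope=0.1, sigma=1.0):
    rng = np.random.default_rng(seed)
    ages = rng.uniform(18, 50, n)
    values = 1.0 + slope * ages + sigma * rng.standard_normal(n)
    return ages, values


def _flat_curves(q_lo, q_mid, q_hi):
    taus = (0.05, 0.5, 0.95)
    coefs = {t: np.array([v, 0.0, 0.0]) for t, v in zip(taus, (q_lo, q_mid, q_hi))}
    cis = {t: np.stack([coefs[t], coefs[t]], axis=1) for t in taus}
    return QuantileCurveSet("f", 2, taus, coefs, cis, 100, (18.0, 50.0))


class TestQuantileCurves:
    def test_constant_values_give_flat_curves_and_zero_width_cis(self, rng):
        ages = rng.uniform(18, 50, 40)
        curves = fit_quantile_curves(ages, np.full(40, 7.0), n_boot=50, seed=0)
        preds = curves.predict(np.array([20.0, 35.0, 49.0]))
        assert np.allclose(preds, 7.0)
        for t in curves.taus:
            assert np.allclose(curves.bootstrap_ci[t][:, 0], curves.bootstrap_ci[t][:, 1])

    def test_gaussian_quantile_distance_and_coverage(self):
        ages, values = _gaussian_sample(2000, seed=1)
        curves = fit_quantile_curves(ages, values, n_boot=0, seed=1)
        mid = curves.predict(34.0)[0]
        assert mid[2] - mid[1] == pytest.approx(1.645, abs=0.15)
        # held-out coverage of the fitted 95th percentile curve
        hold_ages, hold_vals = _gaussian_sample(500, seed=2)
        preds = curves.predict(hold_ages)
        frac_below_q95 = np.mean(hold_vals < preds[:, 2])
        assert 0.93 <= frac_below_q95 <= 0.97

    def test_check_loss_balance_property(self):
        ages, values = _gaussian_sample(800, seed=3)
        curves = fit_quantile_curves(ages, values, n_boot=0, seed=3)
        preds = curves.predict(ages)
        for idx, tau in enumerate(curves.taus):
            frac = np.mean(values < preds[:, idx])
            assert abs(frac - tau) <= 2 / np.sqrt(800)

    def test_degenerate_inputs(self, rng):
        values = rng.standard_normal(40)
        with pytest.raises(np.linalg.LinAlgError):
            fit_quantile_curves(np.full(40, 30.0), values)
        with pytest.raises(ValueError):
            fit_quantile_curves(rng.uniform(18, 50, 40), values, taus=(0.0, 0.5, 0.95))
        with pytest.raises(ValueError):
            fit_quantile_curves(rng.uniform(18, 50, 10), values[:10])  # too few

    def test_non_crossing_after_rearrangement(self):
        ages, values = _gaussian_sample(200, seed=4, sigma=3.0)
        curves = fit_quantile_curves(ages, values, n_boot=0, seed=4)
        preds = curves.predict(np.linspace(18, 50, 40))
        assert np.all(np.diff(preds, axis=1) >= 0)


class TestAggregateModel:
    def test_fold_sizes_and_training_counts(self, rng):
        ages = rng.uniform(18, 50, 91)
        feats = rng.standard_normal((91, 2))
        model = fit_aggregate_normative(ages, feats, ["a", "b"], n_folds=10, seed=0)
        sizes = np.bincount(model.fold_assignment, minlength=10)
        assert set(sizes) <= {9, 10}
        for f in range(10):
            assert model.folds[f]["a"].n_fit == 91 - sizes[f]

    def test_duplicated_data_gives_identical_fold_curves(self, rng):
        # 10 distinct ages, each replicated 10 times: age-decile
        # stratification deals one replicate per fold, so every fold's
        # training data is the same multiset and all curve sets coincide
        base_ages = np.linspace(20, 47, 10)
        ages = np.repeat(base_ages, 10)
        values = np.repeat(2.0 + 0.1 * base_ages + rng.standard_normal(10), 10)
        model = fit_aggregate_normative(ages, values[:, None], ["f"], n_folds=10, seed=1)
        ref = model.folds[0]["f"]
        for fold in model.folds[1:]:
            for t in ref.taus:
                assert np.allclose(fold["f"].coefficients[t], ref.coefficients[t], atol=1e-8)

    def test_too_many_folds(self, rng):
        with pytest.raises(ValueError):
            fit_aggregate_normative(
                rng.uniform(18, 50, 5), rng.standard_normal((5, 1)), ["f"], n_folds=10
            )


class TestDeviationZ:
    def test_direct_formula(self):
        curves = _flat_curves(2.0, 3.0, 6.0)
        assert deviation_z(5.0, 30.0, curves) == pytest.approx(0.5, abs=1e-12)

    def test_median_scores_zero(self):
        curves = _flat_curves(2.0, 3.0, 6.0)
        assert deviation_z(3.0, 30.0, curves) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_scale(self):
        curves = _flat_curves(3.0, 3.0, 3.0)
        with pytest.raises(DegenerateScaleError):
            deviation_z(5.0, 30.0, curves)

    def test_monotone_in_observed_value(self):
        curves = _flat_curves(1.0, 2.0, 4.0)
        zs = [deviation_z(c, 40.0, curves) for c in (0.0, 1.0, 2.5, 7.0)]
        assert all(b > a for a, b in zip(zs, zs[1:]))

    def test_gaussian_closed_form(self):
        # a point at mu + 1.645 sigma scores z = 1.645/3.29 = 0.5
        ages, values = _gaussian_sample(2000, seed=5)
        curves = fit_quantile_curves(ages, values, n_boot=0, seed=5)
        age = 34.0
        mu = 1.0 + 0.1 * age
        z = deviation_z(mu + 1.645, age, curves)
        assert z == pytest.approx(0.5, abs=0.05)

    def test_scaling_equivariance(self):
        ages, values = _gaussian_sample(500, seed=6)
        c1 = fit_quantile_curves(ages, values, n_boot=0, seed=6)
        c2 = fit_quantile_curves(ages, 7.0 * values, n_boot=0, seed=6)
        z1 = deviation_z(values[0], ages[0], c1)
        z2 = deviation_z(7.0 * values[0], ages[0], c2)
        assert z1 == pytest.approx(z2, abs=1e-4)


class TestCohortScoring:
    def test_aggregate_z_is_mean_of_fold_z(self, rng):
        ages = rng.uniform(18, 50, 60)
        feats = 1.0 + 0.05 * ages[:, None] + rng.standard_normal((60, 3))
        model = fit_aggregate_normative(ages, feats, ["a", "b", "c"], n_folds=5, seed=2)
        pats = rng.uniform(20, 48, 8)
        pat_feats = 1.0 + 0.05 * pats[:, None] + rng.standard_normal((8, 3))
        devs = score_cohort([f"p{i}" for i in range(8)], pats, pat_feats, model)
        for d in devs:
            assert np.allclose(d.z, d.per_fold_z.mean(axis=0))
            assert d.z.shape == (3,)

    def test_heldout_controls_centered_near_zero(self):
        ages, values = _gaussian_sample(2000, seed=7)
        model = fit_aggregate_normative(ages, values[:, None], ["f"], n_folds=10, seed=7)
        ids = [f"c{i}" for i in range(2000)]
        devs = score_heldout_controls(ids, ages, values[:, None], model)
        z = np.array([d.z[0] for d in devs])
        assert abs(np.median(z)) < 0.1  # a control at the median scores ~0
        assert abs(np.mean(z > 0) - 0.5) < 0.05

    def test_extrapolation_warns(self, rng):
        ages = rng.uniform(25, 45, 60)
        feats = rng.standard_normal((60, 1)) + 0.1 * ages[:, None]
        model = fit_aggregate_normative(ages, feats, ["f"], n_folds=5, seed=3)
        with pytest.warns(UserWarning, match="extrapolat"):
            score_cohort(["p0"], np.array([60.0]), np.array([[2.0]]), model)
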