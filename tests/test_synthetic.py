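"""Generator contracts: determinism, planted structure, and realism limits."""

import numpy as np
import pytest

from dfcsubtype import (
    extract_feature_vector,
    generate_cohort,
    generate_ground_truth,
    true_subject_components,
)
from dfcsubtype.synthetic import (
    InfeasibleRankError,
    _sample_series,
    load_ground_truth,
    save_ground_truth,
)


def test_ground_truth_deterministic_under_fixed_seed():
    a = generate_ground_truth(5, 20, sparsity=0.1, seed=7)
    b = generate_ground_truth(5, 20, sparsity=0.1, seed=7)
    assert a.component_bank.tobytes() == b.component_bank.tobytes()
    assert a.halo_bank.tobytes() == b.halo_bank.tobytes()
    assert a.age_effect_coefficients.tobytes() == b.age_effect_coefficients.tobytes()
    for s in a.deviation_shifts:
        assert np.array_equal(a.deviation_shifts[s], b.deviation_shifts[s])


def test_cohort_deterministic_and_serialisable(tmp_path):
    gt1 = generate_ground_truth(4, 12, seed=3)
    gt2 = generate_ground_truth(4, 12, seed=3)
    m1, s1 = generate_cohort(gt1, 5, 5, 4, 80, 2.0, 0.1, seed=3)
    m2, s2 = generate_cohort(gt2, 5, 5, 4, 80, 2.0, 0.1, seed=3)
    assert m1.equals(m2)
    for a, b in zip(s1, s2):
        assert a.data.tobytes() == b.data.tobytes()
    save_ground_truth(gt1, tmp_path / "gt.npz")
    loaded = load_ground_truth(tmp_path / "gt.npz")
    assert np.array_equal(loaded.component_bank, gt1.component_bank)
    assert loaded.subtype_labels == gt1.subtype_labels


def test_rank_bound_error():
    with pytest.raises(InfeasibleRankError):
        generate_ground_truth(200, 10)


def test_component_patterns_near_orthogonal():
    gt = generate_ground_truth(5, 20, sparsity=0.1, seed=7)
    vecs = gt.component_edges()
    vecs = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
    cos = vecs @ vecs.T
    off = cos[~np.eye(5, dtype=bool)]
    assert np.max(np.abs(off)) < 0.3
    # patterns symmetric with zero diagonal
    assert np.allclose(gt.component_bank, gt.component_bank.transpose(0, 2, 1))
    assert np.allclose(gt.component_bank[:, np.arange(20), np.arange(20)], 0.0)


def test_cohort_sizes_and_deterministic_subtype_rounding():
    gt = generate_ground_truth(4, 12, seed=1)
    manifest, series = generate_cohort(gt, 91, 91, 125, 210, 2.0, 0.1, seed=1)
    assert len(manifest) == 307
    assert len(series) == 307
    assert all(ts.data.shape == (210, 12) for ts in series)
    counts = manifest.query("group == 'patient'")["subtype_true"].value_counts()
    # round(0.16 * 91) = 15 subtype-I patients, remainder subtype II
    assert counts["I"] == 15
    assert counts["II"] == 76


def test_manifest_field_invariants():
    gt = generate_ground_truth(4, 12, seed=2)
    manifest, _ = generate_cohort(gt, 8, 8, 6, 80, 2.0, 0.1, seed=2)
    patients = manifest["group"] == "patient"
    assert manifest.loc[patients, "illness_duration"].notna().all()
    assert manifest.loc[~patients, "illness_duration"].isna().all()
    assert (manifest.loc[patients, "illness_duration"] >= 0).all()
    assert manifest["age"].between(18, 50).all()
    assert manifest["mean_fd"].ge(0).all() and manifest["max_fd"].ge(0).all()
    assert manifest["subject_id"].is_unique


def test_invalid_arguments():
    gt = generate_ground_truth(4, 12, seed=2)
    with pytest.raises(ValueError):
        generate_cohort(gt, 2, 2, 2, t_volumes=0)
    with pytest.raises(ValueError):
        generate_cohort(gt, 2, 2, 2, t_volumes=80, tr=-1.0)
    with pytest.raises(ValueError):
        generate_ground_truth(3, 12, sparsity=1.5)
    bad_spec = {"proportions": {"I": 0.5, "II": 0.2}, "shifts": {"I": {}, "II": {}}}
    with pytest.raises(ValueError):
        generate_ground_truth(3, 12, subtype_spec=bad_spec)


def test_weight_trajectories_smooth_positive(small_gt, small_cohort):
    manifest, _ = small_cohort
    for sid in manifest["subject_id"][:5]:
        traj = small_gt.weight_trajectories[sid]
        assert np.all(np.isfinite(traj))
        assert np.all(traj >= 0)  # module strengths are non-negative
        for row in traj:
            ac = np.corrcoef(row[:-1], row[1:])[0, 1]
            assert ac > 0.5


def test_noiseless_constant_weight_matches_analytic_correlation():
    """With exactly whitened innovations and constant module strengths, the
    full-series sample correlation equals the analytic correlation of
    Sigma = I + w b b^T to machine precision."""
    rng = np.random.default_rng(0)
    b = np.zeros((1, 8))
    b[0, :4] = [0.8, 0.7, 0.6, 0.5]
    w = np.full((1, 120), 1.3)
    x = _sample_series(b, w, noise_sd=0.0, rng=rng)
    sample_corr = np.corrcoef(x.T)
    sigma = np.eye(8) + 1.3 * np.outer(b[0], b[0])
    d = np.sqrt(np.diag(sigma))
    analytic = sigma / np.outer(d, d)
    assert np.allclose(sample_corr, analytic, atol=1e-10)


def test_noisy_windows_approximate_analytic_correlation():
    """Overlapping sliding windows estimate the same correlation up to
    sampling error of order 1/sqrt(L)."""
    from dfcsubtype import RoiTimeSeries, sliding_window_fc

    rng = np.random.default_rng(1)
    b = np.zeros((1, 8))
    b[0, :4] = [0.8, 0.7, 0.6, 0.5]
    w = np.full((1, 300), 1.3)
    x = _sample_series(b, w, noise_sd=0.0, rng=rng)
    dfc = sliding_window_fc(RoiTimeSeries("s", x, 2.0), window_length_s=60)
    sigma = np.eye(8) + 1.3 * np.outer(b[0], b[0])
    d = np.sqrt(np.diag(sigma))
    iu = np.triu_indices(8, 1)
    analytic_z = np.arctanh((sigma / np.outer(d, d))[iu])
    err = np.abs(dfc.edges.mean(axis=0) - analytic_z)
    assert err.max() < 0.15  # statistical, not numerical, agreement


def test_noiseless_age_trend_recovered_by_feature_extractor():
    """With population jitter disabled, the efficiency features computed on
    the true planted components follow the quadratic age trend (R^2 > 0.95
    after a quadratic fit on controls)."""
    gt = generate_ground_truth(4, 16, sparsity=0.07, seed=5)
    gt.driver_jitter_sd = 0.0
    manifest, _ = generate_cohort(gt, 0, 60, 0, 80, 2.0, 0.0, seed=5)
    ages = manifest["age"].to_numpy()
    ge = np.stack(
        [
            extract_feature_vector(
                true_subject_components(gt, sid, window_volumes=30), 16
            ).ic_measures
            for sid in manifest["subject_id"]
        ]
    )
    for k in range(4):
        coef = np.polyfit(ages, ge[:, k], 2)
        resid = ge[:, k] - np.polyval(coef, ages)
        total = ge[:, k].var()
        if total < 1e-12:  # flat trend drawn for this component
            continue
        assert 1 - resid.var() / total > 0.95
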