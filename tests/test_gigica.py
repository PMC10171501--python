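"""Group decomposition and guided subject back-reconstruction."""

import numpy as np
import pytest

from dfcsubtype import (
    estimate_window_weights,
    fit_group_components,
    fit_subject_components,
)
from dfcsubtype.dfc import DynamicFCSeries, edge_index_pairs
from dfcsubtype.gigica import GroupComponents


def _disjoint_sparse_patterns(n_comp, n_edges, per_comp, rng):
    """Mutually disjoint-support sparse unit patterns (K x E)."""
    patterns = np.zeros((n_comp, n_edges))
    slots = rng.permutation(n_edges)
    for k in range(n_comp):
        idx = slots[k * per_comp : (k + 1) * per_comp]
        patterns[k, idx] = rng.uniform(0.5, 1.0, per_comp)
        patterns[k] /= np.linalg.norm(patterns[k])
    return patterns


def _dfc_from(patterns, weights, rng, noise=0.0, sid="s"):
    edges = weights.T @ patterns
    if noise > 0:
        edges = edges + noise * rng.standard_normal(edges.shape)
    m = int(round((1 + np.sqrt(1 + 8 * patterns.shape[1])) / 2))
    return DynamicFCSeries(sid, edges, 30, 1, edge_index_pairs(m))


class TestGroupComponents:
    def test_noiseless_identifiable_case_recovered(self, rng):
        # data lying exactly in the span of 3 disjoint sparse patterns
        patterns = _disjoint_sparse_patterns(3, 190, 12, rng)
        dfcs = [
            _dfc_from(patterns, 0.5 + rng.random((3, 80)), rng, sid=f"s{i}") for i in range(4)
        ]
        group = fit_group_components(dfcs, k=3, seed=0)
        match = np.abs(patterns @ group.patterns.T)
        # greedy matching: every planted pattern found up to permutation/sign
        assert np.allclose(np.sort(match.max(axis=1)), 1.0, atol=1e-3)

    def test_deterministic_under_fixed_seed(self, rng):
        patterns = _disjoint_sparse_patterns(3, 120, 10, rng)
        dfcs = [_dfc_from(patterns, rng.random((3, 60)), rng, noise=0.05) for _ in range(3)]
        a = fit_group_components(dfcs, k=3, seed=5)
        b = fit_group_components(dfcs, k=3, seed=5)
        assert np.array_equal(a.patterns, b.patterns)

    def test_rank_bound(self, rng):
        patterns = _disjoint_sparse_patterns(2, 50, 8, rng)
        dfcs = [_dfc_from(patterns, rng.random((2, 5)), rng) for _ in range(2)]
        with pytest.raises(np.linalg.LinAlgError):
            fit_group_components(dfcs, k=40)

    def test_pattern_conventions(self, rng):
        patterns = _disjoint_sparse_patterns(3, 120, 10, rng)
        dfcs = [_dfc_from(patterns, rng.random((3, 60)), rng, noise=0.05) for _ in range(3)]
        group = fit_group_components(dfcs, k=3, seed=1)
        norms = np.linalg.norm(group.patterns, axis=1)
        assert np.allclose(norms, 1.0)
        for row in group.patterns:
            assert row[np.argmax(np.abs(row))] > 0
        assert 0 < group.mixing_summary <= 1.0


class TestSubjectComponents:
    def test_pure_reference_limit(self, rng):
        patterns = _disjoint_sparse_patterns(3, 120, 10, rng)
        group = GroupComponents(patterns=patterns, mixing_summary=1.0, k=3)
        dfc = _dfc_from(patterns, rng.random((3, 60)), rng, noise=0.1)
        sc = fit_subject_components(dfc, group, lambda_ref=1.0)
        assert np.allclose(sc.patterns, patterns)
        assert np.all(sc.reference_similarity > 0.999)

    def test_self_consistency_subject_from_group_patterns(self, rng):
        patterns = _disjoint_sparse_patterns(4, 190, 12, rng)
        group = GroupComponents(patterns=patterns, mixing_summary=1.0, k=4)
        dfc = _dfc_from(patterns, 0.5 + rng.random((4, 80)), rng, noise=0.0)
        sc = fit_subject_components(dfc, group, lambda_ref=0.5)
        assert np.all(sc.reference_similarity >= 0.999)
        assert sc.converged.all()

    def test_perturbed_subject_closer_than_reference(self, rng):
        """Planted-perturbation check: when the subject's data come from
        perturbed patterns, the guided estimate is closer to the truth than
        the unperturbed references are, for most components."""
        refs = _disjoint_sparse_patterns(5, 300, 14, rng)
        true = refs.copy()
        for k in range(5):  # perturb within each reference's support
            support = np.flatnonzero(refs[k])
            bump = rng.normal(0, 0.35, support.size)
            true[k, support] = np.abs(refs[k, support] + bump)
            true[k] /= np.linalg.norm(true[k])
        group = GroupComponents(patterns=refs, mixing_summary=1.0, k=5)
        dfc = _dfc_from(true, 0.5 + rng.random((5, 100)), rng, noise=0.01)
        sc = fit_subject_components(dfc, group, lambda_ref=0.3)
        wins = 0
        for k in range(5):
            corr_est = np.corrcoef(sc.patterns[k], true[k])[0, 1]
            corr_ref = np.corrcoef(refs[k], true[k])[0, 1]
            wins += corr_est > corr_ref
        assert wins >= 4  # >= 80% of components

    def test_invalid_lambda(self, rng):
        patterns = _disjoint_sparse_patterns(2, 50, 6, rng)
        group = GroupComponents(patterns=patterns, mixing_summary=1.0, k=2)
        dfc = _dfc_from(patterns, rng.random((2, 40)), rng)
        with pytest.raises(ValueError):
            fit_subject_components(dfc, group, lambda_ref=1.5)


class TestWindowWeights:
    def test_exact_linear_recovery(self, rng):
        patterns = _disjoint_sparse_patterns(2, 80, 10, rng)
        edges = (2.0 * patterns[0] - 1.0 * patterns[1] + 0.7)[None, :]
        dfc = DynamicFCSeries("s", edges, 30, 1, edge_index_pairs(13)[:80])
        weights = estimate_window_weights(dfc, patterns)
        assert abs(weights[0, 0] - 2.0) < 1e-10
        assert abs(weights[1, 0] + 1.0) < 1e-10

    def test_orthonormal_patterns_reduce_to_projection(self, rng):
        patterns = _disjoint_sparse_patterns(3, 90, 10, rng)
        # zero the mean within each disjoint support: rows stay mutually
        # orthogonal and become orthogonal to the intercept column too
        for row in patterns:
            support = row != 0
            row[support] -= row[support].mean()
        patterns /= np.linalg.norm(patterns, axis=1, keepdims=True)
        x = rng.standard_normal(90)
        dfc = DynamicFCSeries("s", x[None, :], 30, 1, edge_index_pairs(14)[:90])
        weights = estimate_window_weights(dfc, patterns)
        # disjoint supports keep the rows orthogonal after centering
        expected = patterns @ x
        assert np.max(np.abs(weights[:, 0] - expected)) < 1e-8

    def test_matches_normal_equations_oracle(self, rng):
        patterns = rng.standard_normal((4, 150))
        patterns /= np.linalg.norm(patterns, axis=1, keepdims=True)
        edges = rng.standard_normal((20, 150))
        dfc = DynamicFCSeries("s", edges, 30, 1, edge_index_pairs(18)[:150])
        weights = estimate_window_weights(dfc, patterns)
        design = np.column_stack([np.ones(150), patterns.T])
        oracle = np.linalg.solve(design.T @ design, design.T @ edges.T)[1:]
        assert np.max(np.abs(weights - oracle)) < 1e-10

    def test_collinear_patterns_rejected(self, rng):
        p = rng.standard_normal(60)
        patterns = np.stack([p, 2 * p])
        dfc = DynamicFCSeries("s", rng.standard_normal((5, 60)), 30, 1, edge_index_pairs(12)[:60])
        with pytest.raises(np.linalg.LinAlgError):
            estimate_window_weights(dfc, patterns)

    def test_reconstruction_error_non_increasing_in_nested_fits(self, rng):
        """OLS residual norm is non-increasing as components are added."""
        patterns = _disjoint_sparse_patterns(4, 120, 10, rng)
        edges = rng.random((4, 50)).T @ patterns + 0.05 * rng.standard_normal((50, 120))
        dfc = DynamicFCSeries("s", edges, 30, 1, edge_index_pairs(16)[:120])
        errors = []
        for j in range(1, 5):
            sub = patterns[:j]
            w = estimate_window_weights(dfc, sub)
            recon = w.T @ sub
            centered = edges - edges.mean(axis=1, keepdims=True)
            resid = centered - (recon - recon.mean(axis=1, keepdims=True))
            errors.append(np.linalg.norm(resid))
        assert all(b <= a + 1e-9 for a, b in zip(errors, errors[1:]))
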