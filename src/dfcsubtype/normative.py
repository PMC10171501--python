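"""Age-referenced normative model of network features.

For each feature, second-order polynomial quantile curves (5th, 50th, 95th
percentiles by default) are fit on healthy controls by pinball-loss
minimisation, with optional bootstrap confidence intervals. Ten-fold
cross-validation yields an aggregate model; a subject's deviation z for a
feature is

    z = (c_real - q50(age)) / (q95(age) - q5(age)),

averaged over the ten fold-models. Controls, when scored for calibration,
use only the model of their own held-out fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning, IterationLimitWarning

__all__ = [
    "QuantileCurveSet",
    "AggregateNormativeModel",
    "DeviationVector",
    "DegenerateScaleError",
    "fit_quantile_curves",
    "fit_aggregate_normative",
    "deviation_z",
    "score_cohort",
    "score_heldout_controls",
]


class DegenerateScaleError(ValueError):
    """The 5th-95th percentile range is non-positive at the requested age."""


def _design(ages: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(ages, degree + 1, increasing=True)


def _fit_pinball(ages: np.ndarray, values: np.ndarray, tau: float, degree: int) -> np.ndarray:
    exog = _design(ages, degree)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", IterationLimitWarning)
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sm.QuantReg(values, exog).fit(q=tau)
    return np.asarray(res.params, dtype=float)


@dataclass
class QuantileCurveSet:
    """Per-feature polynomial quantile curves with bootstrap CIs.

    ``coefficients[tau]`` holds (beta0, ..., beta_degree) in feature units
    versus years; ``bootstrap_ci[tau]`` the 95% percentile interval per
    coefficient (equal bounds when ``n_boot`` was 0 or the fit degenerate).
    Predictions are monotonically rearranged across quantile levels so the
    curves never cross at any evaluated age.
    """

    feature_name: str
    degree: int
    taus: tuple[float, ...]
    coefficients: dict[float, np.ndarray]
    bootstrap_ci: dict[float, np.ndarray]
    n_fit: int
    age_range: tuple[float, float]

    def predict(self, ages: np.ndarray | float) -> np.ndarray:
        """Quantile predictions, shape (n_ages, n_taus), non-crossing."""
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        design = _design(ages, self.degree)
        preds = np.stack([design @ self.coefficients[t] for t in self.taus], axis=1)
        return np.sort(preds, axis=1)  # monotone rearrangement across taus


def fit_quantile_curves(
    ages,
    values,
    taus: tuple[float, ...] = (0.05, 0.50, 0.95),
    degree: int = 2,
    n_boot: int = 1000,
    seed: int = 0,
    feature_name: str = "feature",
) -> QuantileCurveSet:
    """Fit polynomial quantile curves by pinball-loss minimisation.

    Bootstrap CIs use ``n_boot`` seeded case resamples (skipped when 0).
    Degenerate inputs: constant values yield flat curves with zero-width
    CIs; constant ages are a design-rank error.
    """
    ages = np.asarray(ages, dtype=float).ravel()
    values = np.asarray(values, dtype=float).ravel()
    if ages.size != values.size:
        raise ValueError("ages and values differ in length")
    n = ages.size
    if n < 10 * (degree + 1):
        raise ValueError(f"need at least {10 * (degree + 1)} observations, got {n}")
    if np.ptp(ages) == 0:
        raise np.linalg.LinAlgError("constant ages: polynomial design is rank deficient")
    taus = tuple(float(t) for t in taus)
    if any(not 0 < t < 1 for t in taus):
        raise ValueError("quantile levels must lie strictly within (0, 1)")

    ncoef = degree + 1
    if np.ptp(values) == 0:
        flat = np.zeros(ncoef)
        flat[0] = values[0]
        coefs = {t: flat.copy() for t in taus}
        cis = {t: np.stack([flat, flat], axis=1) for t in taus}
        return QuantileCurveSet(
            feature_name, degree, taus, coefs, cis, n, (float(ages.min()), float(ages.max()))
        )

    coefs = {t: _fit_pinball(ages, values, t, degree) for t in taus}
    cis: dict[float, np.ndarray] = {}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        samples = {t: np.empty((n_boot, ncoef)) for t in taus}
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            a_b, v_b = ages[idx], values[idx]
            if np.ptp(a_b) == 0 or np.ptp(v_b) == 0:
                for t in taus:
                    samples[t][b] = coefs[t]
                continue
            for t in taus:
                samples[t][b] = _fit_pinball(a_b, v_b, t, degree)
        for t in taus:
            lo = np.percentile(samples[t], 2.5, axis=0)
            hi = np.percentile(samples[t], 97.5, axis=0)
            cis[t] = np.stack([lo, hi], axis=1)
    else:
        cis = {t: np.stack([coefs[t], coefs[t]], axis=1) for t in taus}

    return QuantileCurveSet(
        feature_name, degree, taus, coefs, cis, n, (float(ages.min()), float(ages.max()))
    )


@dataclass
class AggregateNormativeModel:
    """10-fold ensemble of per-feature quantile-curve sets.

    ``folds[f][feature_name]`` is the curve set fit with fold ``f`` held
    out; ``fold_assignment[i]`` is control i's fold. Patients are scored by
    every fold-model and averaged; a control is scored only by the model
    that never saw it.
    """

    folds: list[dict[str, QuantileCurveSet]]
    fold_assignment: np.ndarray
    feature_names: list[str]
    taus: tuple[float, ...]

    @property
    def n_folds(self) -> int:
        return len(self.folds)


@dataclass
class DeviationVector:
    subject_id: str
    z: np.ndarray  # per-feature deviation, mean over folds
    per_fold_z: np.ndarray  # n_folds x n_features


def _stratified_folds(ages: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment stratified by age decile (round-robin within strata)."""
    n = ages.size
    edges = np.quantile(ages, np.linspace(0, 1, 11)[1:-1])
    strata = np.searchsorted(edges, ages, side="right")
    assignment = np.empty(n, dtype=int)
    offset = int(rng.integers(n_folds))
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            assignment[i] = (offset + pos) % n_folds
        offset += idx.size
    return assignment


def fit_aggregate_normative(
    ages,
    features: np.ndarray,
    feature_names: list[str],
    n_folds: int = 10,
    taus: tuple[float, ...] = (0.05, 0.50, 0.95),
    degree: int = 2,
    n_boot: int = 0,
    seed: int = 0,
) -> AggregateNormativeModel:
    """Fit the fold-ensemble normative model on healthy controls.

    Folds are age-decile stratified and seeded; each fold's curves are fit
    on all controls outside that fold.
    """
    ages = np.asarray(ages, dtype=float).ravel()
    features = np.asarray(features, dtype=float)
    n = ages.size
    if features.shape[0] != n:
        raise ValueError("ages and feature matrix disagree on subject count")
    if n_folds > n:
        raise ValueError(f"cannot split {n} controls into {n_folds} folds")
    rng = np.random.default_rng(seed)
    assignment = _stratified_folds(ages, n_folds, rng)
    counts = np.bincount(assignment, minlength=n_folds)
    if np.any(counts == 0):
        warnings.warn("a fold received no controls; curves for it use all data", stacklevel=2)

    folds: list[dict[str, QuantileCurveSet]] = []
    for f in range(n_folds):
        train = assignment != f
        if not np.any(train):
            train = np.ones(n, dtype=bool)
        curves: dict[str, QuantileCurveSet] = {}
        for j, name in enumerate(feature_names):
            curves[name] = fit_quantile_curves(
                ages[train],
                features[train, j],
                taus=taus,
                degree=degree,
                n_boot=n_boot,
                seed=seed + 7919 * f + j,
                feature_name=name,
            )
        folds.append(curves)
    return AggregateNormativeModel(folds, assignment, list(feature_names), tuple(taus))


def deviation_z(c_real: float, age: float, curves: QuantileCurveSet) -> float:
    """Deviation z of one observation: (c_real - q50) / (q95 - q5).

    'q5'/'q50'/'q95' are the lowest/middle/highest of the curve set's three
    quantile levels; the range between the outer quantiles is the scaling
    coefficient.
    """
    if len(curves.taus) != 3:
        raise ValueError("deviation_z expects a three-quantile curve set")
    q_lo, q_mid, q_hi = curves.predict(age)[0]
    if q_hi <= q_lo:
        raise DegenerateScaleError(
            f"{curves.feature_name}: non-positive quantile range at age {age}"
        )
    return float((c_real - q_mid) / (q_hi - q_lo))


def _score_by_fold(
    model: AggregateNormativeModel, fold: int, ages: np.ndarray, values: np.ndarray
) -> np.ndarray:
    """z-scores of all subjects under one fold-model. values: n x F."""
    out = np.empty_like(values, dtype=float)
    curves_by_name = model.folds[fold]
    for j, name in enumerate(model.feature_names):
        preds = curves_by_name[name].predict(ages)  # n x 3
        scale = preds[:, 2] - preds[:, 0]
        if np.any(scale <= 0):
            raise DegenerateScaleError(f"{name}: non-positive quantile range in fold {fold}")
        out[:, j] = (values[:, j] - preds[:, 1]) / scale
    return out


def score_cohort(
    subject_ids: list[str],
    ages,
    features: np.ndarray,
    model: AggregateNormativeModel,
) -> list[DeviationVector]:
    """Score subjects (typically patients) with all fold-models and average."""
    ages = np.asarray(ages, dtype=float).ravel()
    features = np.asarray(features, dtype=float)
    lo = min(c.age_range[0] for fold in model.folds for c in fold.values())
    hi = max(c.age_range[1] for fold in model.folds for c in fold.values())
    if np.any((ages < lo) | (ages > hi)):
        warnings.warn(
            "some subjects fall outside the fitted age range; scores are extrapolated",
            stacklevel=2,
        )
    per_fold = np.stack(
        [_score_by_fold(model, f, ages, features) for f in range(model.n_folds)], axis=0
    )  # folds x n x F
    mean_z = per_fold.mean(axis=0)
    return [
        DeviationVector(subject_ids[i], mean_z[i], per_fold[:, i, :]) for i in range(ages.size)
    ]


def score_heldout_controls(
    subject_ids: list[str],
    ages,
    features: np.ndarray,
    model: AggregateNormativeModel,
) -> list[DeviationVector]:
    """Score the fitting controls, each by its own held-out fold only."""
    ages = np.asarray(ages, dtype=float).ravel()
    features = np.asarray(features, dtype=float)
    if ages.size != model.fold_assignment.size:
        raise ValueError("these controls do not match the model's fold assignment")
    out: list[DeviationVector] = []
    for f in range(model.n_folds):
        idx = np.flatnonzero(model.fold_assignment == f)
        if idx.size == 0:
            continue
        z = _score_by_fold(model, f, ages[idx], features[idx])
        for row, i in enumerate(idx):
            per_fold = np.full((model.n_folds, features.shape[1]), np.nan)
            per_fold[f] = z[row]
            out.append(DeviationVector(subject_ids[i], z[row], per_fold))
    out.sort(key=lambda d: subject_ids.index(d.subject_id))
    return out
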