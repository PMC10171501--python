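"""Unsupervised subtype discovery on deviation z-scores.

Two stages, both repeated 100 times to expose (and then quantify) the
variability of randomly initialised k-means:

1. wrapper forward feature selection — each run clusters a random subject
   subsample and greedily adds the feature that most improves the mean
   silhouette; features selected in more than 80% of runs are "informative";
2. repeated clustering on the informative features — run labels are aligned
   by Hungarian matching, each subject's certainty is the fraction of runs
   agreeing with its modal label, and low-certainty subjects are excluded
   from post hoc analyses.

The k-means here is deliberately plain Lloyd with uniform random point
initialisation: run-to-run variability is the signal the certainty measure
quantifies, so no careful seeding is wanted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "SelectionResult",
    "ClusterEnsemble",
    "forward_select_features",
    "cluster_ensemble",
    "certainty_from_runs",
    "silhouette_index",
    "kmeans_lloyd",
]

logger = logging.getLogger(__name__)

# Margin by which a candidate must beat its noise baseline for a selection
# step to be accepted. Mean silhouette is nearly dimension-invariant for
# equally informative features (adding a redundant feature of the same
# cluster separation barely moves it), so a raw require-an-improvement rule
# would keep exactly one feature of any informative set, while a fixed
# keep-if-close tolerance admits noise chained behind strong structure.
# From the second step on, the baseline is the same candidate column
# permuted across subjects — marginal preserved, alignment with the
# selected structure destroyed — so informative candidates clear it and
# pure-noise candidates only sporadically do.
SELECTION_PERM_MARGIN = 0.01
# The opening step has no such twin (a reordered single column is the same
# 1-D point set), and any 1-D sample splits with a deceptively high
# silhouette. Selection is therefore gated once per cohort: the best
# single-feature silhouette must exceed the 95th percentile of the same
# maximum computed on Gaussian surrogate matrices (per-column moments
# preserved, unimodal by construction). Without that evidence of any
# clusterable feature, all selection frequencies are zero.
SURROGATE_REPLICATES = 50
SURROGATE_QUANTILE = 0.95


@dataclass
class SelectionResult:
    frequencies: np.ndarray  # per-feature selection rate over runs, in [0, 1]
    informative_features: list[str]
    runs: int
    threshold: float
    feature_names: list[str]
    criterion_trace: list[list[tuple[str, float]]]  # per run: (feature, criterion)

    @property
    def informative_mask(self) -> np.ndarray:
        return self.frequencies > self.threshold


@dataclass
class ClusterEnsemble:
    labels_per_run: np.ndarray  # R x N, aligned to run 0
    final_labels: np.ndarray  # N modal labels
    certainty: np.ndarray  # N values in [1/k, 1]
    excluded_subjects: list[int]  # indices with certainty < threshold
    k: int
    silhouette: float
    center_instability: float
    mean_stability: float

    @property
    def retained_mask(self) -> np.ndarray:
        mask = np.ones(self.final_labels.size, dtype=bool)
        mask[self.excluded_subjects] = False
        return mask


def kmeans_lloyd(
    x: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int = 100,
    max_restarts: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Plain Lloyd k-means with uniform random point initialisation.

    Returns (labels, centers). A run producing an empty cluster is
    re-initialised (bounded retries) and logged.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} points, got {n}")
    for attempt in range(max_restarts):
        centers = x[rng.choice(n, size=k, replace=False)].copy()
        labels = np.full(n, -1, dtype=int)
        empty = False
        for _ in range(max_iter):
            d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            new_labels = d2.argmin(axis=1)
            counts = np.bincount(new_labels, minlength=k)
            if np.any(counts == 0):
                empty = True
                break
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for j in range(k):
                centers[j] = x[labels == j].mean(axis=0)
        if not empty:
            return labels, centers
        logger.debug("k-means produced an empty cluster; re-initialising (attempt %d)", attempt)
    raise RuntimeError(f"k-means failed to avoid empty clusters in {max_restarts} restarts")


def _pairwise_sq_dists(x: np.ndarray) -> np.ndarray:
    sq = (x**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * (x @ x.T)
    np.maximum(d2, 0, out=d2)
    return d2


def _silhouette_from_dists(dist: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Mean silhouette from a precomputed distance matrix (singletons -> 0)."""
    n = labels.size
    counts = np.bincount(labels, minlength=k)
    # sums of distances from each point to every cluster: n x k
    sums = np.zeros((n, k))
    for j in range(k):
        sums[:, j] = dist[:, labels == j].sum(axis=1)
    own = counts[labels]
    s = np.zeros(n)
    valid = own > 1
    a = np.zeros(n)
    a[valid] = sums[valid, labels[valid]] / (own[valid] - 1)
    other = sums / np.maximum(counts, 1)[None, :]
    other[np.arange(n), labels] = np.inf
    other[:, counts == 0] = np.inf
    b = other.min(axis=1)
    denom = np.maximum(a, b)
    ok = valid & np.isfinite(b) & (denom > 0)
    s[ok] = (b[ok] - a[ok]) / denom[ok]
    return float(s.mean())


def silhouette_index(x: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette of a labelled point set (Euclidean distances).

    Each point contributes (b - a)/max(a, b); members of singleton clusters
    contribute 0. Raises if fewer than two clusters are present.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    labels = np.asarray(labels)
    uniq, labels_idx = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("silhouette is undefined for a single cluster")
    dist = np.sqrt(_pairwise_sq_dists(x))
    return _silhouette_from_dists(dist, labels_idx, uniq.size)


def _calinski_from_x(x: np.ndarray, labels: np.ndarray, k: int) -> float:
    n = x.shape[0]
    overall = x.mean(axis=0)
    ssb = 0.0
    ssw = 0.0
    for j in range(k):
        pts = x[labels == j]
        c = pts.mean(axis=0)
        ssb += pts.shape[0] * float(((c - overall) ** 2).sum())
        ssw += float(((pts - c) ** 2).sum())
    if ssw == 0:
        return np.inf
    return (ssb / (k - 1)) / (ssw / (n - k))


def forward_select_features(
    z_matrix: np.ndarray,
    feature_names: list[str] | None = None,
    k: int = 2,
    runs: int = 100,
    threshold: float = 0.8,
    seed: int = 0,
    subsample: float = 0.8,
    criterion: str = "silhouette",
    perm_margin: float = SELECTION_PERM_MARGIN,
) -> SelectionResult:
    """Wrapper forward selection of clustering-informative features.

    Selection is first gated by a cohort-level clusterability test against
    Gaussian surrogates (see SURROGATE_REPLICATES); if no feature shows
    more cluster structure than chance, all frequencies are zero. Otherwise
    each run draws a random ``subsample`` fraction of subjects (the
    repeated cross-validation element) and greedily grows a feature set: at
    each step every remaining feature is evaluated by the clustering
    criterion of a fresh random-init k-means partition on the augmented
    set; the first feature is the criterion maximiser, and later candidates
    are kept only while they beat their own column-permuted twin by
    ``perm_margin``. Ties break toward the lowest feature index. Selection
    frequencies over runs are thresholded (default > 0.8) to give the
    informative set.
    """
    z_matrix = np.atleast_2d(np.asarray(z_matrix, dtype=float))
    n, n_feat = z_matrix.shape
    if n <= k:
        raise ValueError(f"need more than k={k} subjects, got {n}")
    if n_feat < 1 or runs < 1:
        raise ValueError("need at least one feature and one run")
    if criterion not in ("silhouette", "calinski"):
        raise ValueError("criterion must be 'silhouette' or 'calinski'")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(n_feat)]

    rng = np.random.default_rng(seed)
    n_sub = max(k + 1, int(round(subsample * n)))
    counts = np.zeros(n_feat)
    trace: list[list[tuple[str, float]]] = []

    def _single_feature_max(mat: np.ndarray) -> float:
        # gate statistic: mean of the top-3 single-feature criteria, so a
        # cohort with several moderately clustered features is not judged
        # by its single best one alone
        crits = []
        for j in range(mat.shape[1]):
            try:
                labels, _ = kmeans_lloyd(mat[:, [j]], k, rng)
            except RuntimeError:
                continue
            if np.unique(labels).size < 2:
                continue
            if criterion == "silhouette":
                dist = np.abs(mat[:, j][:, None] - mat[:, j][None, :])
                crits.append(_silhouette_from_dists(dist, labels, k))
            else:
                crits.append(_calinski_from_x(mat[:, [j]], labels, k))
        if not crits:
            return -np.inf
        top = sorted(crits, reverse=True)[: min(3, len(crits))]
        return float(np.mean(top))

    # cohort-level clusterability gate (see SURROGATE_REPLICATES)
    observed_max = _single_feature_max(z_matrix)
    mu = z_matrix.mean(axis=0)
    sd = z_matrix.std(axis=0)
    sd[sd == 0] = 1.0
    surrogate_maxima = np.array(
        [
            _single_feature_max(mu + sd * rng.standard_normal(z_matrix.shape))
            for _ in range(SURROGATE_REPLICATES)
        ]
    )
    threshold_gate = float(np.quantile(surrogate_maxima, SURROGATE_QUANTILE))
    if observed_max <= threshold_gate + perm_margin:
        logger.info(
            "selection gate: best single-feature criterion %.3f below surrogate "
            "threshold %.3f; no informative features",
            observed_max,
            threshold_gate,
        )
        return SelectionResult(
            counts, [], runs, threshold, list(feature_names), [[] for _ in range(runs)]
        )

    for _ in range(runs):
        idx = rng.choice(n, size=min(n_sub, n), replace=False)
        x = z_matrix[idx]
        # incremental squared-distance matrices make silhouette cheap per candidate
        per_feat_d2 = None
        if criterion == "silhouette":
            per_feat_d2 = np.stack(
                [(x[:, j][:, None] - x[:, j][None, :]) ** 2 for j in range(n_feat)]
            )
        selected: list[int] = []
        d2_sel = np.zeros((x.shape[0], x.shape[0]))
        run_trace: list[tuple[str, float]] = []

        def _evaluate(col_values: np.ndarray, d2_col: np.ndarray) -> float:
            design = (
                np.column_stack([x[:, selected], col_values]) if selected else col_values[:, None]
            )
            try:
                labels, _ = kmeans_lloyd(design, k, rng)
            except RuntimeError:
                return -np.inf
            if np.unique(labels).size < 2:
                return -np.inf
            if criterion == "silhouette":
                dist = np.sqrt(d2_sel + d2_col)
                return _silhouette_from_dists(dist, labels, k)
            return _calinski_from_x(design, labels, k)

        while len(selected) < n_feat:
            step_best = (-np.inf, -1)
            for j in range(n_feat):
                if j in selected:
                    continue
                crit = _evaluate(x[:, j], per_feat_d2[j] if per_feat_d2 is not None else None)
                if selected:
                    # per-candidate noise baseline: the same column permuted
                    # across subjects, which preserves its marginal but
                    # destroys its alignment with the selected structure. A
                    # candidate is eligible only if it beats its own permuted
                    # twin; a pure-noise column does so only sporadically, so
                    # no noise feature passes consistently across runs.
                    perm = rng.permutation(x.shape[0])
                    d2_col = None
                    if per_feat_d2 is not None:
                        d2_col = per_feat_d2[j][np.ix_(perm, perm)]
                    if crit <= _evaluate(x[perm, j], d2_col) + perm_margin:
                        continue
                if crit > step_best[0]:
                    step_best = (crit, j)
            if step_best[1] < 0:
                break
            j = step_best[1]
            selected.append(j)
            if criterion == "silhouette":
                d2_sel = d2_sel + per_feat_d2[j]
            run_trace.append((feature_names[j], float(step_best[0])))
        counts[selected] += 1
        trace.append(run_trace)

    freqs = counts / runs
    informative = [feature_names[j] for j in range(n_feat) if freqs[j] > threshold]
    return SelectionResult(freqs, informative, runs, threshold, list(feature_names), trace)


def certainty_from_runs(labels_per_run: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject certainty and modal label from aligned run labels.

    certainty_i = max_label count_i(label) / n_runs; the final label is the
    argmax, ties resolved toward the lower label index.
    """
    labels_per_run = np.asarray(labels_per_run)
    runs = labels_per_run.shape[0]
    k = int(labels_per_run.max()) + 1
    counts = np.stack([(labels_per_run == j).sum(axis=0) for j in range(k)], axis=1)
    certainty = counts.max(axis=1) / runs
    final = counts.argmax(axis=1)
    return certainty, final


def _align_to_reference(labels: np.ndarray, reference: np.ndarray, k: int) -> np.ndarray:
    """Relabel ``labels`` to best agree with ``reference`` (Hungarian)."""
    confusion = np.zeros((k, k))
    for a in range(k):
        mask = labels == a
        for b in range(k):
            confusion[a, b] = np.sum(reference[mask] == b)
    rows, cols = linear_sum_assignment(-confusion)
    mapping = dict(zip(rows, cols))
    return np.array([mapping[v] for v in labels], dtype=int)


def cluster_ensemble(
    z_matrix: np.ndarray,
    k: int = 2,
    runs: int = 100,
    certainty_threshold: float = 0.6,
    seed: int = 0,
) -> ClusterEnsemble:
    """Repeated k-means with label alignment, certainty and quality indices.

    ``runs`` independent random-init k-means partitions are aligned to the
    first run by Hungarian matching on the confusion matrix. Per subject,
    certainty = (modal label count)/runs and the final label is the argmax
    (ties toward the lower label index). Subjects below the certainty
    threshold are flagged excluded; silhouette is computed on the retained
    subjects under the final labels; center instability is the mean over
    runs of the summed distances of the run's (aligned) centers from the
    across-run mean centers; mean stability is the mean certainty of the
    retained subjects.
    """
    z_matrix = np.atleast_2d(np.asarray(z_matrix, dtype=float))
    n = z_matrix.shape[0]
    rng = np.random.default_rng(seed)
    all_labels = np.empty((runs, n), dtype=int)
    all_centers = np.empty((runs, k, z_matrix.shape[1]))
    for r in range(runs):
        labels, centers = kmeans_lloyd(z_matrix, k, rng)
        if r > 0:
            aligned = _align_to_reference(labels, all_labels[0], k)
            # permute centers consistently with the relabeling
            perm = np.empty(k, dtype=int)
            for a in range(k):
                mapped = np.unique(aligned[labels == a])
                perm[mapped[0]] = a
            centers = centers[perm]
            labels = aligned
        all_labels[r] = labels
        all_centers[r] = centers

    certainty, final_labels = certainty_from_runs(all_labels)
    excluded = [int(i) for i in np.flatnonzero(certainty < certainty_threshold)]
    retained = np.ones(n, dtype=bool)
    retained[excluded] = False

    if np.unique(final_labels[retained]).size >= 2:
        sil = silhouette_index(z_matrix[retained], final_labels[retained])
    else:
        sil = float("nan")
    mean_centers = all_centers.mean(axis=0)
    instability = float(
        np.mean([np.linalg.norm(all_centers[r] - mean_centers, axis=1).sum() for r in range(runs)])
    )
    mean_stability = float(certainty[retained].mean()) if retained.any() else float("nan")
    return ClusterEnsemble(
        labels_per_run=all_labels,
        final_labels=final_labels,
        certainty=certainty,
        excluded_subjects=excluded,
        k=k,
        silhouette=sil,
        center_instability=instability,
        mean_stability=mean_stability,
    )
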