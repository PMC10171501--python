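"""Group ICA over dynamic-connectivity windows and guided subject fits.

Group stage: all guidance subjects' W x E window matrices are stacked,
column-centred, reduced to K principal components (seeded randomized SVD)
and unmixed by fixed-point negentropy maximisation (FastICA, logcosh
contrast), giving K component patterns in edge space. Because connectivity
components are sparse by nature, each pattern is then sparsified at a
relative threshold (loadings below a fraction of the component's peak are
zeroed) — the denoising step that makes the patterns usable as guides.

Subject stage (guided back-reconstruction): each subject-specific pattern
is the group reference refined by the subject's own connectivity on the
reference's active edge set,

    p_k  =  normalise( lambda_ref * r_k  +  (1 - lambda_ref) * s_k ),

where r_k is the group reference and s_k is the subject's mean
Fisher-z connectivity map restricted to the support of r_k (sign-aligned
and normalised). The support restriction carries the reference's sparsity
prior into the subject estimate: off-support edges contribute estimation
noise but no identifiable component signal at a single subject's data size.
Time-varying component weights are then per-window ordinary least squares
of the window's edge vector on the K refined patterns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.utils.extmath import randomized_svd

from ._utils import child_seed, pearson
from .dfc import DynamicFCSeries

__all__ = [
    "GroupComponents",
    "SubjectComponents",
    "fit_group_components",
    "fit_subject_components",
    "estimate_window_weights",
]

logger = logging.getLogger(__name__)


def _canonicalise(patterns: np.ndarray) -> np.ndarray:
    """Unit L2 rows; sign such that each row's max-magnitude entry is positive."""
    patterns = np.asarray(patterns, dtype=float)
    norms = np.linalg.norm(patterns, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    out = patterns / norms
    for row in out:
        peak = np.argmax(np.abs(row))
        if row[peak] < 0:
            row *= -1.0
    return out


@dataclass
class GroupComponents:
    patterns: np.ndarray  # K x E, unit rows, sign-fixed, sparsified
    mixing_summary: float  # variance fraction retained by the K-dim reduction
    k: int


@dataclass
class SubjectComponents:
    subject_id: str
    patterns: np.ndarray  # K x E, unit rows, sign-aligned to the guides
    weights: np.ndarray  # K x W per-window OLS coefficients
    reference_similarity: np.ndarray  # K Pearson correlations to the guides
    converged: np.ndarray  # K booleans (False where the data term degenerated)
    n_iter: np.ndarray  # K iteration counts


def fit_group_components(
    dfc_list: list[DynamicFCSeries],
    k: int,
    seed: int = 0,
    sparsify_rel: float = 0.4,
) -> GroupComponents:
    """Group-level spatial ICA on stacked window matrices.

    Rows (windows across subjects) are observations mixing K edge-space
    sources; reduction to K dimensions uses a seeded randomized SVD and the
    unmixing is FastICA with the logcosh contrast. Loadings below
    ``sparsify_rel`` times each component's peak magnitude are zeroed.
    Patterns are returned unit-norm with each row's peak entry positive.
    """
    if len(dfc_list) < 2:
        raise ValueError("group ICA needs at least 2 subjects")
    stacked = np.vstack([d.edges for d in dfc_list])
    n_rows, n_edges = stacked.shape
    if k > min(n_rows, n_edges):
        raise np.linalg.LinAlgError(
            f"K={k} exceeds the rank bound min(windows={n_rows}, edges={n_edges})"
        )
    stacked = stacked - stacked.mean(axis=0)
    total_var = float((stacked**2).sum())
    u, s, vt = randomized_svd(stacked, n_components=k, random_state=child_seed(seed, "group_svd"))
    if s[-1] <= 1e-10 * s[0]:
        raise np.linalg.LinAlgError(f"stacked data has rank below K={k}")
    retained = float((s**2).sum() / total_var) if total_var > 0 else 1.0
    reduced = s[:, None] * vt  # K x E spatial representation

    ica = FastICA(
        n_components=k,
        fun="logcosh",
        whiten="unit-variance",
        max_iter=2000,
        tol=1e-7,
        random_state=child_seed(seed, "group_ica"),
    )
    sources = ica.fit_transform(reduced.T)  # E x K, sources over edges
    patterns = sources.T.copy()
    if sparsify_rel > 0:
        for row in patterns:
            row[np.abs(row) <= sparsify_rel * np.abs(row).max()] = 0.0
    patterns = _canonicalise(patterns)
    return GroupComponents(patterns=patterns, mixing_summary=retained, k=k)


def fit_subject_components(
    dfc: DynamicFCSeries,
    group: GroupComponents,
    lambda_ref: float = 0.5,
    mask_rel: float = 0.05,
) -> SubjectComponents:
    """Guided back-reconstruction of subject-specific component patterns.

    For each component the data term is the subject's mean Fisher-z
    connectivity restricted to the reference's active edges (magnitude above
    ``mask_rel`` of the reference peak), normalised and sign-aligned to the
    reference; the subject pattern blends it with the reference at
    ``lambda_ref`` (1.0 returns the references unchanged, 0.0 trusts the
    subject data alone on the reference support). A component whose data
    term is degenerate (all-zero on the support) falls back to the
    reference and is flagged in ``converged``.
    """
    if not 0 <= lambda_ref <= 1:
        raise ValueError("lambda_ref must lie in [0, 1]")
    if group.k < 1:
        raise ValueError("need at least one group component")
    n_edges = dfc.edges.shape[1]
    if group.patterns.shape[1] != n_edges:
        raise ValueError("group patterns and dFC series disagree on edge count")
    mean_map = dfc.edges.mean(axis=0)
    patterns = np.empty((group.k, n_edges))
    converged = np.ones(group.k, dtype=bool)
    for comp in range(group.k):
        ref = group.patterns[comp]
        mask = np.abs(ref) > mask_rel * np.abs(ref).max()
        data_term = np.where(mask, mean_map, 0.0)
        norm = np.linalg.norm(data_term)
        if norm == 0:
            logger.warning(
                "subject %s component %d: degenerate data term, using reference",
                dfc.subject_id,
                comp,
            )
            converged[comp] = False
            patterns[comp] = ref
            continue
        data_term = data_term / norm
        if float(data_term @ ref) < 0:
            data_term = -data_term
        blended = lambda_ref * ref + (1.0 - lambda_ref) * data_term
        patterns[comp] = blended / np.linalg.norm(blended)

    similarity = np.array([pearson(patterns[c], group.patterns[c]) for c in range(group.k)])
    weights = estimate_window_weights(dfc, patterns)
    return SubjectComponents(
        subject_id=dfc.subject_id,
        patterns=patterns,
        weights=weights,
        reference_similarity=similarity,
        converged=converged,
        n_iter=np.ones(group.k, dtype=int),
    )


def estimate_window_weights(dfc: DynamicFCSeries, patterns: np.ndarray) -> np.ndarray:
    """Per-window OLS of the edge vector on the component patterns.

    The design includes an intercept; the returned K x W matrix holds the
    pattern coefficients only.
    """
    patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
    k, n_edges = patterns.shape
    if dfc.edges.shape[1] != n_edges:
        raise ValueError("pattern edge dimension does not match the dFC series")
    if np.linalg.matrix_rank(patterns) < k:
        raise np.linalg.LinAlgError("component patterns are collinear")
    design = np.column_stack([np.ones(n_edges), patterns.T])  # E x (K+1)
    coeffs, *_ = np.linalg.lstsq(design, dfc.edges.T, rcond=None)
    return coeffs[1:, :]
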