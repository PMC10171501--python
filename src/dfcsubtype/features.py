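"""Scalar network features per component: global efficiency and fluctuation.

A subject is summarised by 2K numbers: for each of the K components, the
global efficiency of the weighted graph defined by its edge loadings, and
the mean absolute frame-to-frame change of its time-varying weight
trajectory. At K = 20 this is the 40-dimensional feature vector the
normative model scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .dfc import edges_to_matrix

__all__ = [
    "FeatureVector",
    "global_efficiency",
    "fluctuation_coefficient",
    "extract_feature_vector",
    "feature_names",
]


@dataclass
class FeatureVector:
    subject_id: str
    ic_measures: np.ndarray  # K global efficiencies, each in [0, 1]
    fluct_coeffs: np.ndarray  # K mean |frame-wise weight change|, >= 0
    feature_names: list[str]

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.ic_measures, self.fluct_coeffs])


def feature_names(k: int) -> list[str]:
    return [f"ge_IC{i + 1:02d}" for i in range(k)] + [f"fc_IC{i + 1:02d}" for i in range(k)]


def global_efficiency(pattern: np.ndarray, m: int, threshold: float = 0.0) -> float:
    """Global efficiency of the weighted graph given by an edge-loading vector.

    Connection weights are |loading| max-normalised to [0, 1] (making the
    measure invariant to pattern rescaling); edge lengths are the reciprocal
    weights; efficiency is the mean inverse shortest-path length over ordered
    node pairs, with unreachable pairs contributing 0. Loadings with
    normalised magnitude <= ``threshold`` are treated as absent.
    """
    pattern = np.asarray(pattern, dtype=float)
    if pattern.shape != (m * (m - 1) // 2,):
        raise ValueError(f"pattern length {pattern.size} does not match m={m}")
    if not np.all(np.isfinite(pattern)):
        raise ValueError("pattern contains non-finite loadings")
    magnitude = np.abs(pattern)
    peak = magnitude.max()
    if peak == 0:
        warnings.warn("all-zero component pattern; global efficiency set to 0", stacklevel=2)
        return 0.0
    weights = magnitude / peak
    if threshold > 0:
        weights = np.where(weights > threshold, weights, 0.0)
    adj = edges_to_matrix(weights, m)
    with np.errstate(divide="ignore"):
        lengths = np.where(adj > 0, 1.0 / adj, 0.0)  # 0 = absent for csgraph
    dist = shortest_path(lengths, method="D", directed=False)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist) & (dist > 0), 1.0 / dist, 0.0)
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (m * (m - 1)))


def fluctuation_coefficient(weights_k: np.ndarray) -> float:
    """Mean absolute first difference of a weight trajectory."""
    weights_k = np.asarray(weights_k, dtype=float).ravel()
    if weights_k.size < 2:
        raise ValueError("need a trajectory of at least 2 windows")
    return float(np.mean(np.abs(np.diff(weights_k))))


def extract_feature_vector(sc, m: int, threshold: float = 0.0) -> FeatureVector:
    """Apply both measures to every component of a SubjectComponents.

    ``sc`` needs ``subject_id``, ``patterns`` (K x E) and ``weights`` (K x W).
    """
    patterns = np.asarray(sc.patterns, dtype=float)
    weights = np.asarray(sc.weights, dtype=float)
    k = patterns.shape[0]
    if weights.shape[0] != k:
        raise ValueError("patterns and weights disagree on component count")
    ge = np.array([global_efficiency(patterns[i], m, threshold=threshold) for i in range(k)])
    fc = np.array([fluctuation_coefficient(weights[i]) for i in range(k)])
    return FeatureVector(
        subject_id=sc.subject_id,
        ic_measures=ge,
        fluct_coeffs=fc,
        feature_names=feature_names(k),
    )
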