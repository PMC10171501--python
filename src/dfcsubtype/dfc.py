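"""Sliding-window dynamic functional connectivity in edge-vector form.

Each subject's T x m series becomes a W x E matrix of Fisher-transformed
window correlations, E = m(m-1)/2 upper-triangle edges in lexicographic
order. With window length L volumes and step s, W = floor((T - L)/s) + 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import RoiTimeSeries

__all__ = [
    "DynamicFCSeries",
    "DegenerateWindowError",
    "sliding_window_fc",
    "edge_index_pairs",
    "edges_to_matrix",
]

R_CLAMP = 1.0 - 1e-7  # Fisher z of |r| = 1 is infinite; clamp keeps it finite


class DegenerateWindowError(ValueError):
    """A ROI is constant within a window, so its correlations are undefined."""


@dataclass
class DynamicFCSeries:
    subject_id: str
    edges: np.ndarray  # W x E Fisher-z values
    window_length_volumes: int
    step_volumes: int
    edge_index: np.ndarray  # E x 2 (i, j), i < j, 0-based ROI indices

    @property
    def n_windows(self) -> int:
        return self.edges.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[1]

    @property
    def n_rois(self) -> int:
        e = self.n_edges
        m = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
        assert m * (m - 1) // 2 == e
        return m


def edge_index_pairs(m: int) -> np.ndarray:
    """Lexicographic upper-triangle (i, j) pairs, i < j, 0-based."""
    iu = np.triu_indices(m, k=1)
    return np.stack(iu, axis=1)


def edges_to_matrix(edges: np.ndarray, m: int) -> np.ndarray:
    """Un-vectorise an E-length edge vector into a symmetric m x m matrix."""
    mat = np.zeros((m, m), dtype=float)
    iu = np.triu_indices(m, k=1)
    mat[iu] = edges
    return mat + mat.T


def _window_weights(length: int, taper: str) -> np.ndarray | None:
    if taper == "none":
        return None
    if taper == "gaussian":
        # Gaussian taper over the window, sigma = L/4 (3 on an L=12 window scale)
        t = np.arange(length) - (length - 1) / 2.0
        w = np.exp(-0.5 * (t / (length / 4.0)) ** 2)
        return w / w.sum()
    raise ValueError(f"unknown taper {taper!r}")


def _window_correlation(
    block: np.ndarray, weights: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    if weights is None:
        centered = block - block.mean(axis=0)
        cov = centered.T @ centered
    else:
        mean = weights @ block
        centered = block - mean
        cov = (centered * weights[:, None]).T @ centered
    sd = np.sqrt(np.diag(cov))
    denom = np.outer(sd, sd)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / denom
    return corr, sd


def sliding_window_fc(
    ts: RoiTimeSeries,
    window_length_s: float = 60.0,
    step_volumes: int = 1,
    taper: str = "none",
) -> DynamicFCSeries:
    """Compute windowed Pearson correlations and vectorise the upper triangle.

    The window length is ``round(window_length_s / tr)`` volumes (a 60 s
    window at TR = 2 s spans 30 volumes). Correlations are clamped to
    |r| <= 1 - 1e-7 before the Fisher transform so all entries stay finite.

    Raises
    ------
    DegenerateWindowError
        if any ROI is constant within any window.
    """
    length = int(round(window_length_s / ts.tr))
    if length < 3:
        raise ValueError(
            f"window of {window_length_s}s at TR={ts.tr}s spans {length} volumes; need >= 3"
        )
    t_total = ts.n_volumes
    if t_total < length:
        raise ValueError(f"series has {t_total} volumes, shorter than window of {length}")
    if step_volumes < 1:
        raise ValueError("step_volumes must be >= 1")

    m = ts.n_rois
    iu = np.triu_indices(m, k=1)
    weights = _window_weights(length, taper)
    starts = range(0, t_total - length + 1, step_volumes)
    rows = []
    for w_idx, start in enumerate(starts):
        block = ts.data[start : start + length]
        corr, sd = _window_correlation(block, weights)
        if np.any(sd == 0):
            roi = int(np.argmax(sd == 0))
            raise DegenerateWindowError(
                f"subject {ts.subject_id}: ROI {ts.roi_labels[roi]!r} is constant "
                f"in window {w_idx} (volumes {start}-{start + length - 1})"
            )
        r = np.clip(corr[iu], -R_CLAMP, R_CLAMP)
        rows.append(np.arctanh(r))
    edges = np.asarray(rows, dtype=float)
    return DynamicFCSeries(
        subject_id=ts.subject_id,
        edges=edges,
        window_length_volumes=length,
        step_volumes=step_volumes,
        edge_index=edge_index_pairs(m),
    )
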