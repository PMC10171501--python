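"""Synthetic cohort generator with ground truth at every pipeline stage.

The generator emulates the latent structure the analysis assumes: a bank of
K sparse, near-orthogonal connectivity components; per-subject smooth
time-varying component weights; BOLD-like ROI series; quadratic age trends
in the latent per-component drivers; and two planted patient subtypes that
differ in deviation magnitude on a subset of features.

Each component is a node module — a subset of ROIs sharing a latent signal,
the standard factor model of a resting-state network. The series is

    x(t) = eps(t) + sum_k sqrt(w_k(t)) * b_k * f_k(t),

with unit node noise eps, i.i.d. module signals f_k and non-negative
time-varying module strengths w_k(t), so the covariance
Sigma(t) = I + sum_k w_k(t) b_k b_k^T is positive definite by construction
at any signal amplitude. The edge-space component pattern is the
off-diagonal part of b_k b_k^T: sparse (within-module edges only) and
near-orthogonal across modules with distinct node sets.

Two latent drivers per component carry all individual variation:

* density driver (-> global-efficiency features): scales the loadings of a
  module's peripheral nodes, so denser modules have more strong edges and
  higher global efficiency;
* volatility driver (-> fluctuation features): scales the amplitude of a
  narrowband oscillation in the module-strength trajectory, the part of the
  weight dynamics that survives window-averaging as frame-wise change.

Subtype shifts are specified in z units of the control population (a shift
of 1.5 moves a driver by 1.5 x the 5th-95th percentile control range of the
driver) and applied additively, on top of the quadratic age trend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np
import pandas as pd

from ._utils import substream
from .features import feature_names as make_feature_names

__all__ = [
    "GroundTruth",
    "InfeasibleRankError",
    "default_subtype_spec",
    "generate_ground_truth",
    "generate_cohort",
    "true_subject_components",
    "save_ground_truth",
    "load_ground_truth",
]


class InfeasibleRankError(ValueError):
    """More components requested than the edge space can hold."""


# --- generator scale constants -------------------------------------------
# Module loadings are set so static within-module correlations land in the
# 0.2-0.5 range typical of resting-state networks; the factor construction
# keeps Sigma(t) positive definite at any amplitude. See docs/methods.md.
CORE_LOAD_RANGE = (0.6, 0.9)  # loadings of a module's core nodes
PERI_LOAD_RANGE = (0.45, 0.7)  # peripheral-node loadings at density 1
SLOW_SD = 0.9  # SD of the slow log-strength drift (smoothed, stationary)
SLOW_SMOOTH_FRACTION = 0.5  # smoothing width as a fraction of the window length
OSC_AMPLITUDE = 0.8  # log-strength oscillation amplitude at volatility 1
OSC_PERIOD_RANGE = (45.0, 105.0)  # volumes
BASE_WEIGHT_MEAN = 1.2  # mean module strength w0
BASE_WEIGHT_SD = 0.25
DRIVER_JITTER_SD = 0.06  # control-population SD of both latent drivers
DRIVER_TREND_AMPLITUDE = 0.08  # linear age-trend coefficient scale
Z_RANGE = 3.29  # 5th-95th percentile range of a standard Gaussian, in SDs

AGE_RANGE = (18.0, 50.0)
AGE_CENTER = 34.0
AGE_SCALE = 16.0

# demographics follow the cohort summary statistics of the study population
EDUCATION_MEAN, EDUCATION_SD = 12.0, 3.3
MALE_FRACTION = 0.65
MEAN_FD_LOC, MEAN_FD_SD = 0.07, 0.04
DURATION_LOGMEAN = {"I": 2.4, "II": 2.9}  # subtype I: shorter illness duration
DURATION_LOGSD = 1.0


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream recovery checks."""

    component_bank: np.ndarray  # K x m x m symmetric, zero diagonal, sparse
    halo_bank: np.ndarray  # K x m x m density-sensitive part of the bank
    age_effect_coefficients: np.ndarray  # 2K x 3: driver trend in scaled age u
    deviation_shifts: dict[str, np.ndarray]  # subtype -> 2K z-unit shifts
    subtype_proportions: dict[str, float]
    seed: int
    sparsity: float
    driver_jitter_sd: float = DRIVER_JITTER_SD
    core_loadings: np.ndarray | None = None  # K x m module loadings (fixed part)
    peri_loadings: np.ndarray | None = None  # K x m peripheral loadings (density-scaled)
    weight_trajectories: dict[str, np.ndarray] = field(default_factory=dict)  # sid -> K x T
    subtype_labels: dict[str, str] = field(default_factory=dict)
    latent_drivers: dict[str, np.ndarray] = field(default_factory=dict)  # sid -> 2K
    subject_patterns: dict[str, np.ndarray] = field(default_factory=dict)  # sid -> K x m x m

    @property
    def n_components(self) -> int:
        return self.component_bank.shape[0]

    @property
    def n_rois(self) -> int:
        return self.component_bank.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return make_feature_names(self.n_components)

    def component_edges(self, bank: np.ndarray | None = None) -> np.ndarray:
        """Edge-vector view (K x E) of a component bank."""
        bank = self.component_bank if bank is None else bank
        iu = np.triu_indices(self.n_rois, k=1)
        return bank[:, iu[0], iu[1]]


def default_subtype_spec(k_true: int) -> dict:
    """Two subtypes mirroring the study's reported structure.

    Subtype I (16% of patients) carries large deviations, subtype II (84%)
    weak ones, on 12 features drawn from 10 components: the efficiency
    measures of components 1-9 and the fluctuation coefficients of
    components 2, 6 and 10 (trimmed to the available bank size).
    """
    names = make_feature_names(k_true)
    affected = [f"ge_IC{i:02d}" for i in range(1, min(9, k_true) + 1)]
    affected += [f"fc_IC{i:02d}" for i in (2, 6, 10) if i <= k_true]
    # deviations point downward (reduced efficiency / damped weight
    # volatility), the direction that keeps both latent maps monotone
    shifts_i = {name: -4.5 for name in affected}
    shifts_ii = {name: -0.25 for name in affected}
    assert set(affected) <= set(names)
    return {
        "proportions": {"I": 0.16, "II": 0.84},
        "shifts": {"I": shifts_i, "II": shifts_ii},
    }


def _spec_to_shift_vectors(spec: dict, names: list[str]) -> tuple[dict, dict]:
    proportions = {k: float(v) for k, v in spec["proportions"].items()}
    total = sum(proportions.values())
    if not np.isclose(total, 1.0):
        raise ValueError(f"subtype proportions sum to {total}, expected 1")
    shifts: dict[str, np.ndarray] = {}
    index = {name: j for j, name in enumerate(names)}
    for subtype, mapping in spec["shifts"].items():
        vec = np.zeros(len(names))
        for feat, value in mapping.items():
            if isinstance(feat, (int, np.integer)):
                vec[int(feat)] = value
            elif feat in index:
                vec[index[feat]] = value
            else:
                raise ValueError(f"unknown feature {feat!r} in subtype spec")
        shifts[subtype] = vec
    if set(shifts) != set(proportions):
        raise ValueError("subtype_spec shifts and proportions name different subtypes")
    return proportions, shifts


def _module_pattern(b: np.ndarray) -> np.ndarray:
    """Zero-diagonal outer product: the edge pattern of one module."""
    mat = np.outer(b, b)
    np.fill_diagonal(mat, 0.0)
    return mat


def generate_ground_truth(
    k_true: int,
    m: int,
    sparsity: float = 0.025,
    subtype_spec: dict | None = None,
    seed: int = 0,
    max_redraws: int = 200,
) -> GroundTruth:
    """Draw the latent module bank and population-level effect structure.

    Each component is a node module whose size is chosen so its within-module
    edge count is roughly ``sparsity`` of the edge space. Core nodes carry
    fixed strong loadings; peripheral nodes carry weaker loadings scaled by
    the subject's density driver. Modules are redrawn until their edge
    patterns are mutually near-orthogonal (pairwise |cosine| < 0.3), keeping
    recovery well posed.
    """
    if k_true < 1 or m < 3:
        raise ValueError("need k_true >= 1 and m >= 3")
    if not 0 < sparsity < 1:
        raise ValueError("sparsity must lie in (0, 1)")
    e_total = m * (m - 1) // 2
    if k_true > e_total:
        raise InfeasibleRankError(
            f"{k_true} components cannot be linearly independent in an "
            f"edge space of dimension {e_total} (m={m})"
        )
    rng = substream(seed, "ground_truth")
    # module size s: s(s-1)/2 within-module edges ~ sparsity * E
    s = int(round((1.0 + np.sqrt(1.0 + 8.0 * sparsity * e_total)) / 2.0))
    s = max(3, min(s, m))
    # small strong core, larger density-scaled periphery: most of a module's
    # edges then carry the density driver, which individual-deviation
    # readouts must detect
    n_core = max(2, int(round(s / 3)))
    n_peri = max(1, s - n_core)
    iu = np.triu_indices(m, k=1)

    core = np.zeros((k_true, m))
    peri = np.zeros((k_true, m))
    edge_vecs = np.zeros((k_true, e_total))
    for k in range(k_true):
        for _ in range(max_redraws):
            nodes = rng.choice(m, size=n_core + n_peri, replace=False)
            b_core = np.zeros(m)
            b_peri = np.zeros(m)
            b_core[nodes[:n_core]] = rng.uniform(*CORE_LOAD_RANGE, size=n_core)
            b_peri[nodes[n_core:]] = rng.uniform(*PERI_LOAD_RANGE, size=n_peri)
            vec = _module_pattern(b_core + b_peri)[iu]
            if k == 0:
                break
            cosines = (edge_vecs[:k] @ vec) / (
                np.linalg.norm(edge_vecs[:k], axis=1) * np.linalg.norm(vec)
            )
            if np.max(np.abs(cosines)) < 0.3:
                break
        else:
            raise RuntimeError("could not draw a near-orthogonal module bank")
        core[k], peri[k] = b_core, b_peri
        edge_vecs[k] = vec

    # bank at baseline density 1; halo = the density-sensitive remainder
    bank = np.stack([_module_pattern(core[k] + peri[k]) for k in range(k_true)])
    halo = bank - np.stack([_module_pattern(core[k]) for k in range(k_true)])

    # quadratic age trends of the latent drivers, in scaled age u = (age-34)/16
    n_feat = 2 * k_true
    coeffs = np.zeros((n_feat, 3))
    coeffs[:, 0] = 1.0
    coeffs[:, 1] = rng.uniform(-DRIVER_TREND_AMPLITUDE, DRIVER_TREND_AMPLITUDE, size=n_feat)
    coeffs[:, 2] = rng.uniform(-DRIVER_TREND_AMPLITUDE, 0.3 * DRIVER_TREND_AMPLITUDE, size=n_feat)

    spec = subtype_spec if subtype_spec is not None else default_subtype_spec(k_true)
    proportions, shifts = _spec_to_shift_vectors(spec, make_feature_names(k_true))
    return GroundTruth(
        component_bank=bank,
        halo_bank=halo,
        age_effect_coefficients=coeffs,
        deviation_shifts=shifts,
        subtype_proportions=proportions,
        seed=int(seed),
        sparsity=float(sparsity),
        core_loadings=core,
        peri_loadings=peri,
    )


def _driver_trend(coeffs: np.ndarray, age: float) -> np.ndarray:
    u = (age - AGE_CENTER) / AGE_SCALE
    return coeffs[:, 0] + coeffs[:, 1] * u + coeffs[:, 2] * u * u


def _subtype_counts(proportions: dict[str, float], n: int) -> dict[str, int]:
    """Deterministic rounding; the last (largest) subtype absorbs the rest."""
    names = sorted(proportions, key=lambda s: proportions[s])
    counts = {}
    assigned = 0
    for name in names[:-1]:
        counts[name] = int(round(proportions[name] * n))
        assigned += counts[name]
    counts[names[-1]] = n - assigned
    return counts


def _weight_trajectories(
    gt: GroundTruth, volatility: np.ndarray, t_total: int, smooth: int, rng: np.random.Generator
) -> np.ndarray:
    """Baseline + stationary smoothed drift + volatility-scaled oscillation.

    The slow drift is moving-average-smoothed white noise (a stationary
    process): random walks are avoided because independent walks are
    spuriously cross-correlated over a few hundred volumes, which would make
    the component weight matrix near-collinear and the decomposition
    unidentifiable. Each component also carries a narrowband oscillation
    whose amplitude encodes the subject's volatility driver — the part of
    the trajectory that survives window-averaging as frame-wise change.
    """
    k = gt.n_components
    w0 = np.abs(rng.normal(BASE_WEIGHT_MEAN, BASE_WEIGHT_SD, size=k))
    width = max(2, int(round(smooth * SLOW_SMOOTH_FRACTION)))
    kernel = np.ones(width) / width
    base = rng.normal(0.0, 1.0, size=(k, t_total + width))
    slow = np.stack([np.convolve(b, kernel, mode="valid")[:t_total] for b in base])
    slow *= SLOW_SD * np.sqrt(width)  # restore unit variance, then scale
    periods = rng.uniform(*OSC_PERIOD_RANGE, size=k)
    phases = rng.uniform(0, 2 * np.pi, size=k)
    t = np.arange(t_total)
    osc = np.sin(2 * np.pi * t[None, :] / periods[:, None] + phases[:, None])
    osc *= (OSC_AMPLITUDE * np.maximum(volatility, 0.0))[:, None] * np.sqrt(2.0)
    # log-strength modulation keeps module strengths positive and smooth
    log_mod = slow + osc
    return w0[:, None] * np.exp(log_mod - 0.5 * log_mod.var(axis=1, keepdims=True))


def _sample_series(
    b_loadings: np.ndarray, weights: np.ndarray, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Sample the factor model x_t = eps_t + sum_k sqrt(w_k(t)) b_k f_kt.

    ``b_loadings`` is K x m, ``weights`` K x T (non-negative). The induced
    covariance I + sum_k w_k(t) b_k b_k^T is positive definite by
    construction. With noise_sd = 0 the joint innovations (node noise and
    module signals) are exactly whitened over the full series, so the
    full-series sample covariance equals the analytic covariance whenever
    the weights are constant.
    """
    k, t_total = weights.shape
    m = b_loadings.shape[1]
    innov = rng.standard_normal((t_total, m + k))
    if noise_sd == 0 and t_total > m + k:
        innov = innov - innov.mean(axis=0)
        cov = innov.T @ innov / t_total
        innov = innov @ np.linalg.inv(np.linalg.cholesky(cov)).T
    eps = innov[:, :m]
    factors = innov[:, m:]  # T x K module signals
    series = eps + (np.sqrt(weights.T) * factors) @ b_loadings
    if noise_sd > 0:
        series = series + noise_sd * rng.standard_normal(series.shape)
    return series


def generate_cohort(
    ground_truth: GroundTruth,
    n_patients: int = 91,
    n_controls_base: int = 91,
    n_controls_ica: int = 125,
    t_volumes: int = 210,
    tr: float = 2.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    window_length_s: float = 60.0,
) -> tuple[pd.DataFrame, list]:
    """Generate manifest rows and ROI time series for a full cohort.

    Groups: ``patient`` (planted subtypes), ``control_base`` (normative
    reference and matching pool) and ``control_ica`` (group-ICA guidance
    sample). Patient drivers carry the subtype's z-unit deviation shifts on
    top of the quadratic age trend shared by everyone. The manifest carries
    a ``subtype_true`` column for patients — the planted label used by
    recovery checks, which the pipeline itself never reads.
    """
    from .io import RoiTimeSeries  # local import to avoid a cycle

    if t_volumes <= 0 or tr <= 0:
        raise ValueError("t_volumes and tr must be positive")
    smooth = int(round(window_length_s / tr))
    if t_volumes < smooth:
        raise ValueError(f"need at least {smooth} volumes (one window), got {t_volumes}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    gt = ground_truth
    k = gt.n_components
    rng = substream(seed, "cohort")

    counts = _subtype_counts(gt.subtype_proportions, n_patients)
    subtype_order = [s for s in sorted(counts) for _ in range(counts[s])]
    rng.shuffle(subtype_order)

    groups = (
        [("patient", i) for i in range(n_patients)]
        + [("control_base", i) for i in range(n_controls_base)]
        + [("control_ica", i) for i in range(n_controls_ica)]
    )
    prefix = {"patient": "pat", "control_base": "ctlb", "control_ica": "ctli"}
    rows = []
    series_list = []
    iu = np.triu_indices(gt.n_rois, k=1)
    sigma_j = gt.driver_jitter_sd
    for group, idx in groups:
        sid = f"{prefix[group]}-{idx + 1:04d}"
        age = float(rng.uniform(*AGE_RANGE))
        sex = "M" if rng.random() < MALE_FRACTION else "F"
        education = float(np.clip(rng.normal(EDUCATION_MEAN, EDUCATION_SD), 3.0, 22.0))
        mean_fd = float(np.abs(rng.normal(MEAN_FD_LOC, MEAN_FD_SD)) + 0.005)
        max_fd = float(mean_fd * rng.uniform(3.0, 8.0))
        subtype = None
        duration = np.nan
        if group == "patient":
            subtype = subtype_order[idx]
            duration = float(rng.lognormal(DURATION_LOGMEAN[subtype], DURATION_LOGSD))

        drivers = _driver_trend(gt.age_effect_coefficients, age)
        drivers = drivers + rng.normal(0.0, sigma_j, size=2 * k)
        if subtype is not None:
            drivers = drivers + gt.deviation_shifts[subtype] * Z_RANGE * sigma_j
        density, volatility = drivers[:k], drivers[k:]

        # density scales each module's peripheral loadings around baseline 1
        b_subj = gt.core_loadings + np.maximum(density, 0.05)[:, None] * gt.peri_loadings
        patterns = np.stack([_module_pattern(b_subj[k_]) for k_ in range(k)])
        weights = _weight_trajectories(gt, volatility, t_volumes, smooth, rng)
        data = _sample_series(b_subj, weights, noise_sd, rng)

        gt.weight_trajectories[sid] = weights
        gt.latent_drivers[sid] = drivers
        gt.subject_patterns[sid] = patterns
        if subtype is not None:
            gt.subtype_labels[sid] = subtype

        rows.append(
            {
                "subject_id": sid,
                "group": group,
                "age": age,
                "sex": sex,
                "education": education,
                "illness_duration": duration,
                "mean_fd": mean_fd,
                "max_fd": max_fd,
                "subtype_true": subtype,
            }
        )
        series_list.append(RoiTimeSeries(subject_id=sid, data=data, tr=tr))

    manifest = pd.DataFrame(rows)
    return manifest, series_list


def true_subject_components(
    gt: GroundTruth, subject_id: str, window_volumes: int = 30, step_volumes: int = 1
):
    """Noise-free SubjectComponents stand-in built directly from ground truth.

    Patterns are the subject's planted component matrices in edge-vector
    form; weights are the planted trajectories averaged within each sliding
    window (what a perfect windowed estimator would see). Feeds the feature
    extractor for generator/extractor self-consistency checks.
    """
    iu = np.triu_indices(gt.n_rois, k=1)
    patterns = gt.subject_patterns[subject_id][:, iu[0], iu[1]]
    traj = gt.weight_trajectories[subject_id]
    t_total = traj.shape[1]
    n_win = (t_total - window_volumes) // step_volumes + 1
    weights = np.stack(
        [
            traj[:, s : s + window_volumes].mean(axis=1)
            for s in range(0, t_total - window_volumes + 1, step_volumes)
        ],
        axis=1,
    )
    assert weights.shape[1] == n_win
    return SimpleNamespace(subject_id=subject_id, patterns=patterns, weights=weights)


def save_ground_truth(gt: GroundTruth, path) -> None:
    """Bundle the ground truth into one compressed array container."""
    sids = sorted(gt.weight_trajectories)
    arrays = {
        "component_bank": gt.component_bank,
        "halo_bank": gt.halo_bank,
        "core_loadings": gt.core_loadings,
        "peri_loadings": gt.peri_loadings,
        "age_effect_coefficients": gt.age_effect_coefficients,
        "seed": np.array([gt.seed]),
        "sparsity": np.array([gt.sparsity]),
        "driver_jitter_sd": np.array([gt.driver_jitter_sd]),
        "subject_ids": np.array(sids),
        "subtype_names": np.array(sorted(gt.subtype_proportions)),
        "subtype_proportions": np.array(
            [gt.subtype_proportions[s] for s in sorted(gt.subtype_proportions)]
        ),
        "deviation_shifts": np.stack(
            [gt.deviation_shifts[s] for s in sorted(gt.deviation_shifts)]
        ),
        "subtype_labels": np.array([gt.subtype_labels.get(s, "") for s in sids]),
    }
    if sids:
        arrays["weight_trajectories"] = np.stack([gt.weight_trajectories[s] for s in sids])
        arrays["latent_drivers"] = np.stack([gt.latent_drivers[s] for s in sids])
    np.savez_compressed(path, **arrays)


def load_ground_truth(path) -> GroundTruth:
    with np.load(path, allow_pickle=False) as data:
        subtype_names = [str(s) for s in data["subtype_names"]]
        gt = GroundTruth(
            component_bank=data["component_bank"],
            halo_bank=data["halo_bank"],
            core_loadings=data["core_loadings"],
            peri_loadings=data["peri_loadings"],
            age_effect_coefficients=data["age_effect_coefficients"],
            deviation_shifts={
                s: data["deviation_shifts"][i] for i, s in enumerate(sorted(subtype_names))
            },
            subtype_proportions={
                s: float(data["subtype_proportions"][i]) for i, s in enumerate(subtype_names)
            },
            seed=int(data["seed"][0]),
            sparsity=float(data["sparsity"][0]),
            driver_jitter_sd=float(data["driver_jitter_sd"][0]),
        )
        sids = [str(s) for s in data["subject_ids"]]
        if sids and "weight_trajectories" in data:
            for i, sid in enumerate(sids):
                gt.weight_trajectories[sid] = data["weight_trajectories"][i]
                gt.latent_drivers[sid] = data["latent_drivers"][i]
                label = str(data["subtype_labels"][i])
                if label:
                    gt.subtype_labels[sid] = label
    return gt
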