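"""Head-motion quality control and covariate matching of controls.

QC applies the study's frame-wise-displacement rule, printed as a
disjunction: keep a subject if mean FD <= 0.5 mm OR max FD <= 2 mm (an
``and`` variant is available since the printed logic is ambiguous).
Matching selects one control per patient by greedy nearest-neighbour on
standardised covariates (Mahalanobis distance, sex matched exactly when
possible), without replacement, in seeded random patient order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._utils import substream

__all__ = [
    "InfeasibleMatchingError",
    "qc_filter_fd",
    "match_controls",
    "standardized_mean_difference",
]


class InfeasibleMatchingError(ValueError):
    """Fewer controls than patients: 1:1 matching without reuse impossible."""


def qc_filter_fd(
    manifest: pd.DataFrame,
    mean_fd_max: float = 0.5,
    max_fd_max: float = 2.0,
    rule: str = "or",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a manifest into (kept, excluded) by the FD rule.

    Never mutates the input; both outputs preserve the input row order.
    """
    for col in ("mean_fd", "max_fd"):
        if col not in manifest.columns:
            raise ValueError(f"manifest lacks required FD column {col!r}")
        if manifest[col].isna().any() or (manifest[col] < 0).any():
            raise ValueError(f"column {col!r} contains missing or negative values")
    pass_mean = manifest["mean_fd"] <= mean_fd_max
    pass_max = manifest["max_fd"] <= max_fd_max
    if rule == "or":
        keep = pass_mean | pass_max
    elif rule == "and":
        keep = pass_mean & pass_max
    else:
        raise ValueError("rule must be 'or' or 'and'")
    return manifest[keep].copy(), manifest[~keep].copy()


def standardized_mean_difference(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d-style standardised mean difference between two samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def match_controls(
    patients: pd.DataFrame,
    controls: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex", "education"),
    seed: int = 0,
) -> pd.DataFrame:
    """Greedy 1:1 nearest-neighbour matching without replacement.

    Continuous covariates are standardised over the pooled sample and
    combined by Mahalanobis distance; ``sex`` (if listed) restricts each
    patient's candidate pool to same-sex controls whenever any remain.
    Returns the matched control rows, one per patient, in patient order,
    with a ``matched_to`` column naming the patient.
    """
    if len(controls) < len(patients):
        raise InfeasibleMatchingError(
            f"{len(controls)} controls cannot cover {len(patients)} patients 1:1"
        )
    use_sex = "sex" in covariates
    continuous = [c for c in covariates if c != "sex"]
    for col in covariates:
        for df, name in ((patients, "patients"), (controls, "controls")):
            if col not in df.columns:
                raise ValueError(f"{name} lack covariate column {col!r}")

    pooled = pd.concat([patients[continuous], controls[continuous]], axis=0)
    mean = pooled.mean(axis=0).to_numpy(dtype=float)
    sd = pooled.std(axis=0, ddof=1).to_numpy(dtype=float)
    sd[sd == 0] = 1.0
    pat_x = (patients[continuous].to_numpy(dtype=float) - mean) / sd
    ctl_x = (controls[continuous].to_numpy(dtype=float) - mean) / sd
    pooled_std = np.vstack([pat_x, ctl_x])
    if pooled_std.shape[1] > 1:
        cov = np.cov(pooled_std, rowvar=False)
        cov_inv = np.linalg.pinv(cov)
    else:
        cov_inv = np.eye(1)

    rng = substream(seed, "matching")
    order = rng.permutation(len(patients))
    available = np.ones(len(controls), dtype=bool)
    ctl_sex = controls["sex"].to_numpy() if use_sex else None
    pat_sex = patients["sex"].to_numpy() if use_sex else None
    chosen = np.full(len(patients), -1, dtype=int)
    for i in order:
        delta = ctl_x - pat_x[i]
        d2 = np.einsum("ij,jk,ik->i", delta, cov_inv, delta)
        candidates = available.copy()
        if use_sex:
            same_sex = candidates & (ctl_sex == pat_sex[i])
            if same_sex.any():
                candidates = same_sex
        d2 = np.where(candidates, d2, np.inf)
        pick = int(np.argmin(d2))
        chosen[i] = pick
        available[pick] = False

    matched = controls.iloc[chosen].copy()
    matched["matched_to"] = patients["subject_id"].to_numpy()
    matched.index = range(len(matched))
    return matched
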