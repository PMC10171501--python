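"""End-to-end orchestration of the subtype-discovery analysis.

Stage order: QC -> control matching -> sliding-window dFC -> group ICA on
the guidance controls -> guided subject ICA -> network features ->
normative model on the base controls -> deviation scoring -> feature
selection + ensemble clustering of patients -> covariate-adjusted
permutation contrasts. Every stage draws from a named substream of the
root seed, logs its wall time, and can persist/reload its artifacts so a
run is resumable from any stage.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import child_seed
from .config import PipelineConfig
from .dfc import DynamicFCSeries, edge_index_pairs, sliding_window_fc
from .features import extract_feature_vector, feature_names
from .gigica import GroupComponents, SubjectComponents, fit_group_components, fit_subject_components
from .inference import permutation_ttest_adjusted
from .io import (
    RoiTimeSeries,
    load_arrays,
    load_json,
    read_manifest,
    save_arrays,
    save_json,
    write_manifest,
)
from .normative import (
    AggregateNormativeModel,
    QuantileCurveSet,
    fit_aggregate_normative,
    score_cohort,
    score_heldout_controls,
)
from .qc import match_controls, qc_filter_fd
from .subtype import ClusterEnsemble, SelectionResult, cluster_ensemble, forward_select_features

__all__ = ["PipelineState", "STAGES", "run_full_pipeline", "run_stage"]

logger = logging.getLogger(__name__)

STAGES = [
    "qc",
    "match",
    "dfc",
    "group_ica",
    "subject_ica",
    "features",
    "normative",
    "subtype",
    "stats",
]


class StageError(RuntimeError):
    """A stage failed; carries the stage name and subject context."""


@dataclass
class PipelineState:
    """Mutable bundle of all pipeline inputs and intermediates."""

    config: PipelineConfig
    manifest: pd.DataFrame
    series: dict[str, RoiTimeSeries] = field(default_factory=dict)

    qc_kept: pd.DataFrame | None = None
    qc_excluded: pd.DataFrame | None = None
    analysis_manifest: pd.DataFrame | None = None  # patients + matched base + ica
    dfc: dict[str, DynamicFCSeries] = field(default_factory=dict)
    group_components: GroupComponents | None = None
    subject_components: dict[str, SubjectComponents] = field(default_factory=dict)
    features: pd.DataFrame | None = None  # subject_id, group + 2K feature columns
    normative_model: AggregateNormativeModel | None = None
    zscores: pd.DataFrame | None = None  # patients x 2K deviations
    control_zscores: pd.DataFrame | None = None
    selection: SelectionResult | None = None
    ensemble: ClusterEnsemble | None = None
    subtype_labels: pd.DataFrame | None = None
    stats: dict[str, pd.DataFrame] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)

    # -- convenience ------------------------------------------------------
    def patients(self) -> pd.DataFrame:
        src = self.analysis_manifest if self.analysis_manifest is not None else self.manifest
        return src[src["group"] == "patient"]

    def feature_matrix(self, group: str) -> tuple[list[str], np.ndarray]:
        names = feature_names(self.config.n_components)
        rows = self.features[self.features["group"] == group]
        return list(rows["subject_id"]), rows[names].to_numpy(dtype=float)


# --------------------------------------------------------------------------
# stages


def _stage_qc(state: PipelineState) -> None:
    cfg = state.config
    kept, excluded = qc_filter_fd(state.manifest, cfg.mean_fd_max, cfg.max_fd_max, cfg.fd_rule)
    state.qc_kept, state.qc_excluded = kept, excluded
    logger.info("qc: kept %d / excluded %d subjects", len(kept), len(excluded))


def _stage_match(state: PipelineState) -> None:
    kept = state.qc_kept
    patients = kept[kept["group"] == "patient"]
    base_pool = kept[kept["group"] == "control_base"]
    ica = kept[kept["group"] == "control_ica"]
    matched = match_controls(
        patients, base_pool, seed=child_seed(state.config.seed, "matching")
    ).drop(columns=["matched_to"])
    state.analysis_manifest = pd.concat([patients, matched, ica], ignore_index=True)
    logger.info(
        "match: %d patients, %d matched base controls, %d ICA controls",
        len(patients),
        len(matched),
        len(ica),
    )


def _stage_dfc(state: PipelineState) -> None:
    cfg = state.config
    state.dfc = {}
    for sid in state.analysis_manifest["subject_id"]:
        try:
            state.dfc[sid] = sliding_window_fc(
                state.series[sid], cfg.window_length_s, cfg.step_volumes, cfg.taper
            )
        except Exception as exc:  # noqa: BLE001 - re-raise with subject context
            raise StageError(f"stage dfc failed for subject {sid}: {exc}") from exc
    any_dfc = next(iter(state.dfc.values()))
    logger.info("dfc: %d subjects, %d windows x %d edges", len(state.dfc), any_dfc.n_windows, any_dfc.n_edges)


def _stage_group_ica(state: PipelineState) -> None:
    cfg = state.config
    ica_ids = state.analysis_manifest.query("group == 'control_ica'")["subject_id"]
    dfc_list = [state.dfc[sid] for sid in ica_ids]
    state.group_components = fit_group_components(
        dfc_list,
        cfg.n_components,
        seed=child_seed(cfg.seed, "group_ica"),
        sparsify_rel=cfg.sparsify_rel,
    )
    logger.info(
        "group_ica: K=%d, retained variance %.3f",
        cfg.n_components,
        state.group_components.mixing_summary,
    )


def _stage_subject_ica(state: PipelineState) -> None:
    cfg = state.config
    state.subject_components = {}
    ids = state.analysis_manifest.query("group in ('patient', 'control_base')")["subject_id"]
    for sid in ids:
        try:
            state.subject_components[sid] = fit_subject_components(
                state.dfc[sid],
                state.group_components,
                lambda_ref=cfg.lambda_ref,
                mask_rel=cfg.mask_rel,
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"stage subject_ica failed for subject {sid}: {exc}") from exc
    n_flag = sum(int((~sc.converged).sum()) for sc in state.subject_components.values())
    n_low = sum(
        int((sc.reference_similarity < cfg.reference_floor).sum())
        for sc in state.subject_components.values()
    )
    if n_low:
        logger.warning(
            "subject_ica: %d component fits fell below the reference-similarity "
            "floor %.2f",
            n_low,
            cfg.reference_floor,
        )
    logger.info("subject_ica: %d subjects fit, %d degenerate components", len(ids), n_flag)


def _stage_features(state: PipelineState) -> None:
    m = next(iter(state.dfc.values())).n_rois  # recoverable from edge count
    names = feature_names(state.config.n_components)
    rows = []
    meta = state.analysis_manifest.set_index("subject_id")
    for sid, sc in state.subject_components.items():
        fv = extract_feature_vector(sc, m)
        rows.append({"subject_id": sid, "group": meta.loc[sid, "group"], **dict(zip(names, fv.values))})
    state.features = pd.DataFrame(rows)
    logger.info("features: %d subjects x %d features", len(rows), len(names))


def _stage_normative(state: PipelineState) -> None:
    cfg = state.config
    names = feature_names(cfg.n_components)
    meta = state.analysis_manifest.set_index("subject_id")
    ctl_ids, ctl_x = state.feature_matrix("control_base")
    ctl_ages = meta.loc[ctl_ids, "age"].to_numpy(dtype=float)
    taus = tuple(p / 100.0 for p in cfg.percentiles)
    state.normative_model = fit_aggregate_normative(
        ctl_ages,
        ctl_x,
        names,
        n_folds=cfg.n_folds,
        taus=taus,
        degree=cfg.normative_degree,
        n_boot=cfg.n_boot,
        seed=child_seed(cfg.seed, "normative"),
    )
    pat_ids, pat_x = state.feature_matrix("patient")
    pat_ages = meta.loc[pat_ids, "age"].to_numpy(dtype=float)
    devs = score_cohort(pat_ids, pat_ages, pat_x, state.normative_model)
    state.zscores = pd.DataFrame(
        [{"subject_id": d.subject_id, **dict(zip(names, d.z))} for d in devs]
    )
    ctl_devs = score_heldout_controls(ctl_ids, ctl_ages, ctl_x, state.normative_model)
    state.control_zscores = pd.DataFrame(
        [{"subject_id": d.subject_id, **dict(zip(names, d.z))} for d in ctl_devs]
    )
    logger.info("normative: scored %d patients, %d controls", len(pat_ids), len(ctl_ids))


def _stage_subtype(state: PipelineState) -> None:
    cfg = state.config
    names = feature_names(cfg.n_components)
    z = state.zscores[names].to_numpy(dtype=float)
    state.selection = forward_select_features(
        z,
        feature_names=names,
        k=cfg.k,
        runs=cfg.n_cluster_runs,
        threshold=cfg.selection_frequency_threshold,
        seed=child_seed(cfg.seed, "selection"),
        subsample=cfg.selection_subsample,
        criterion=cfg.selection_criterion,
        perm_margin=cfg.selection_perm_margin,
    )
    informative = state.selection.informative_features
    if not informative:
        raise StageError("stage subtype: no feature exceeded the selection-frequency threshold")
    z_inf = state.zscores[informative].to_numpy(dtype=float)
    state.ensemble = cluster_ensemble(
        z_inf,
        k=cfg.k,
        runs=cfg.n_cluster_runs,
        certainty_threshold=cfg.certainty_threshold,
        seed=child_seed(cfg.seed, "ensemble"),
    )
    # name clusters by deviation magnitude: subtype I = larger mean |z|
    ens = state.ensemble
    order = np.argsort(
        [-np.abs(z_inf[ens.final_labels == j]).mean() for j in range(cfg.k)]
    )
    roman = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"]
    name_of = {int(cluster): roman[rank] for rank, cluster in enumerate(order)}
    state.subtype_labels = pd.DataFrame(
        {
            "subject_id": state.zscores["subject_id"],
            "cluster": ens.final_labels,
            "subtype": [name_of[int(c)] for c in ens.final_labels],
            "certainty": ens.certainty,
            "retained": ens.retained_mask,
        }
    )
    logger.info(
        "subtype: informative=%s, sizes=%s, silhouette=%.3f, stability=%.3f",
        informative,
        np.bincount(ens.final_labels, minlength=cfg.k).tolist(),
        ens.silhouette,
        ens.mean_stability,
    )


def _stage_stats(state: PipelineState) -> None:
    cfg = state.config
    names = feature_names(cfg.n_components)
    meta = state.analysis_manifest.set_index("subject_id")
    labels = state.subtype_labels.set_index("subject_id")

    def block(ids: list[str], z_df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        z = z_df.set_index("subject_id").loc[ids, names].to_numpy(dtype=float)
        cov = np.column_stack(
            [
                meta.loc[ids, "age"].to_numpy(dtype=float),
                (meta.loc[ids, "sex"] == "M").to_numpy(dtype=float),
                meta.loc[ids, "education"].to_numpy(dtype=float),
            ]
        )
        return z, cov

    retained = labels[labels["retained"]]
    groups = {
        "control": list(state.control_zscores["subject_id"]),
        "subtype_I": list(retained[retained["subtype"] == "I"].index),
        "subtype_II": list(retained[retained["subtype"] == "II"].index),
    }
    z_by_group = {
        "control": state.control_zscores,
        "subtype_I": state.zscores,
        "subtype_II": state.zscores,
    }
    contrasts = [
        ("control", "subtype_I"),
        ("control", "subtype_II"),
        ("subtype_I", "subtype_II"),
    ]
    state.stats = {}
    for name_a, name_b in contrasts:
        ids_a, ids_b = groups[name_a], groups[name_b]
        if len(ids_a) < 2 or len(ids_b) < 2:
            logger.warning("stats: skipping %s vs %s (too few subjects)", name_a, name_b)
            continue
        za, cov_a = block(ids_a, z_by_group[name_a])
        zb, cov_b = block(ids_b, z_by_group[name_b])
        res = permutation_ttest_adjusted(
            np.vstack([za, zb]),
            np.array([0] * len(ids_a) + [1] * len(ids_b)),
            covariates=np.vstack([cov_a, cov_b]),
            n_perm=cfg.n_permutations,
            alpha=cfg.alpha_edge,
            seed=child_seed(cfg.seed, f"stats:{name_a}|{name_b}"),
            feature_ids=names,
        )
        state.stats[f"{name_a}_vs_{name_b}"] = res.to_table()

    # illness duration between subtypes, covariate-adjusted like the rest
    pats = [sid for sub in ("I", "II") for sid in groups[f"subtype_{sub}"]]
    dur = meta.loc[pats, "illness_duration"].to_numpy(dtype=float)
    if len(groups["subtype_I"]) >= 2 and len(groups["subtype_II"]) >= 2 and np.isfinite(dur).all():
        grp = np.array([0] * len(groups["subtype_I"]) + [1] * len(groups["subtype_II"]))
        _, cov = block(pats, state.zscores)
        res = permutation_ttest_adjusted(
            dur[:, None],
            grp,
            covariates=cov,
            n_perm=cfg.n_permutations,
            alpha=0.05,
            seed=child_seed(cfg.seed, "stats:duration"),
            feature_ids=["illness_duration"],
        )
        state.stats["duration_I_vs_II"] = res.to_table()
    logger.info("stats: %d contrast tables", len(state.stats))


_STAGE_FUNCS = {
    "qc": _stage_qc,
    "match": _stage_match,
    "dfc": _stage_dfc,
    "group_ica": _stage_group_ica,
    "subject_ica": _stage_subject_ica,
    "features": _stage_features,
    "normative": _stage_normative,
    "subtype": _stage_subtype,
    "stats": _stage_stats,
}


def run_stage(state: PipelineState, stage: str) -> None:
    """Run one named stage on the state, logging its wall time."""
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; valid: {STAGES}")
    start = time.perf_counter()
    try:
        _STAGE_FUNCS[stage](state)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage {stage} failed: {exc}") from exc
    state.timings[stage] = time.perf_counter() - start
    logger.info("stage %s finished in %.2f s (seed %d)", stage, state.timings[stage], state.config.seed)


def run_full_pipeline(
    config: PipelineConfig,
    manifest: pd.DataFrame,
    series: list[RoiTimeSeries] | dict[str, RoiTimeSeries],
    out_dir: str | Path | None = None,
    stages: list[str] | None = None,
    state: PipelineState | None = None,
) -> PipelineState:
    """Execute the pipeline (or a tail of it, on a resumed state).

    Persists every intermediate under ``out_dir`` when given; with
    ``stages`` a subset can be (re)run on a supplied or reloaded state.
    """
    if isinstance(series, list):
        series = {ts.subject_id: ts for ts in series}
    if state is None:
        state = PipelineState(config=config, manifest=manifest, series=series)
    else:
        state.series = series or state.series
    for stage in stages or STAGES:
        run_stage(state, stage)
        if out_dir is not None:
            save_state(state, out_dir)
    return state


# --------------------------------------------------------------------------
# persistence


def _curves_to_json(model: AggregateNormativeModel) -> dict:
    return {
        "taus": list(model.taus),
        "feature_names": model.feature_names,
        "fold_assignment": model.fold_assignment.tolist(),
        "folds": [
            {
                name: {
                    "degree": c.degree,
                    "n_fit": c.n_fit,
                    "age_range": list(c.age_range),
                    "coefficients": {str(t): c.coefficients[t].tolist() for t in c.taus},
                    "bootstrap_ci": {str(t): c.bootstrap_ci[t].tolist() for t in c.taus},
                }
                for name, c in fold.items()
            }
            for fold in model.folds
        ],
    }


def _curves_from_json(data: dict) -> AggregateNormativeModel:
    taus = tuple(data["taus"])
    folds = []
    for fold in data["folds"]:
        curves = {}
        for name, c in fold.items():
            curves[name] = QuantileCurveSet(
                feature_name=name,
                degree=int(c["degree"]),
                taus=taus,
                coefficients={t: np.array(c["coefficients"][str(t)]) for t in taus},
                bootstrap_ci={t: np.array(c["bootstrap_ci"][str(t)]) for t in taus},
                n_fit=int(c["n_fit"]),
                age_range=tuple(c["age_range"]),
            )
        folds.append(curves)
    return AggregateNormativeModel(
        folds=folds,
        fold_assignment=np.array(data["fold_assignment"], dtype=int),
        feature_names=list(data["feature_names"]),
        taus=taus,
    )


def save_state(state: PipelineState, out_dir: str | Path) -> None:
    """Persist every produced intermediate under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state.config.to_yaml(out / "config.yaml")
    write_manifest(state.manifest, out / "manifest.csv")
    if state.qc_kept is not None:
        write_manifest(state.qc_kept, out / "qc_kept.csv")
        write_manifest(state.qc_excluded, out / "qc_excluded.csv")
    if state.analysis_manifest is not None:
        write_manifest(state.analysis_manifest, out / "analysis_manifest.csv")
    if state.dfc:
        sids = sorted(state.dfc)
        first = state.dfc[sids[0]]
        save_arrays(
            out / "dfc.npz",
            subject_ids=np.array(sids),
            edges=np.stack([state.dfc[s].edges for s in sids]),
            edge_index=first.edge_index,
            meta=np.array([first.window_length_volumes, first.step_volumes]),
        )
    if state.group_components is not None:
        save_arrays(
            out / "group_components.npz",
            patterns=state.group_components.patterns,
            mixing_summary=np.array([state.group_components.mixing_summary]),
        )
    if state.subject_components:
        sids = sorted(state.subject_components)
        scs = [state.subject_components[s] for s in sids]
        save_arrays(
            out / "subject_components.npz",
            subject_ids=np.array(sids),
            patterns=np.stack([sc.patterns for sc in scs]),
            weights=np.stack([sc.weights for sc in scs]),
            reference_similarity=np.stack([sc.reference_similarity for sc in scs]),
            converged=np.stack([sc.converged for sc in scs]),
            n_iter=np.stack([sc.n_iter for sc in scs]),
        )
    if state.features is not None:
        state.features.to_csv(out / "features.csv", index=False)
    if state.normative_model is not None:
        save_json(_curves_to_json(state.normative_model), out / "normative_model.json")
        state.zscores.to_csv(out / "zscores.csv", index=False)
        state.control_zscores.to_csv(out / "control_zscores.csv", index=False)
    if state.selection is not None and state.ensemble is not None:
        ens = state.ensemble
        save_json(
            {
                "selection": {
                    "frequencies": dict(
                        zip(state.selection.feature_names, state.selection.frequencies)
                    ),
                    "informative_features": state.selection.informative_features,
                    "runs": state.selection.runs,
                    "threshold": state.selection.threshold,
                },
                "clustering": {
                    "k": ens.k,
                    "silhouette": ens.silhouette,
                    "center_instability": ens.center_instability,
                    "mean_stability": ens.mean_stability,
                    "excluded_subjects": ens.excluded_subjects,
                },
            },
            out / "subtype_results.json",
        )
        save_arrays(out / "labels_per_run.npz", labels=ens.labels_per_run)
        state.subtype_labels.to_csv(out / "subtype_labels.csv", index=False)
    if state.stats:
        for name, table in state.stats.items():
            table.to_csv(out / f"stats_{name}.csv", index=False)
    save_json(state.timings, out / "timings.json")


def load_state(out_dir: str | Path, series: dict[str, RoiTimeSeries] | None = None) -> PipelineState:
    """Reload a persisted state; numeric intermediates become live objects."""
    out = Path(out_dir)
    config = PipelineConfig.from_yaml(out / "config.yaml")
    state = PipelineState(config=config, manifest=read_manifest(out / "manifest.csv"))
    if series:
        state.series = dict(series)
    if (out / "qc_kept.csv").exists():
        state.qc_kept = read_manifest(out / "qc_kept.csv")
        state.qc_excluded = read_manifest(out / "qc_excluded.csv")
    if (out / "analysis_manifest.csv").exists():
        state.analysis_manifest = read_manifest(out / "analysis_manifest.csv")
    if (out / "dfc.npz").exists():
        data = load_arrays(out / "dfc.npz")
        length, step = (int(v) for v in data["meta"])
        for i, sid in enumerate(str(s) for s in data["subject_ids"]):
            state.dfc[sid] = DynamicFCSeries(
                subject_id=sid,
                edges=data["edges"][i],
                window_length_volumes=length,
                step_volumes=step,
                edge_index=data["edge_index"],
            )
    if (out / "group_components.npz").exists():
        data = load_arrays(out / "group_components.npz")
        state.group_components = GroupComponents(
            patterns=data["patterns"],
            mixing_summary=float(data["mixing_summary"][0]),
            k=data["patterns"].shape[0],
        )
    if (out / "subject_components.npz").exists():
        data = load_arrays(out / "subject_components.npz")
        for i, sid in enumerate(str(s) for s in data["subject_ids"]):
            state.subject_components[sid] = SubjectComponents(
                subject_id=sid,
                patterns=data["patterns"][i],
                weights=data["weights"][i],
                reference_similarity=data["reference_similarity"][i],
                converged=data["converged"][i],
                n_iter=data["n_iter"][i],
            )
    if (out / "features.csv").exists():
        state.features = pd.read_csv(out / "features.csv")
    if (out / "normative_model.json").exists():
        state.normative_model = _curves_from_json(load_json(out / "normative_model.json"))
        state.zscores = pd.read_csv(out / "zscores.csv")
        state.control_zscores = pd.read_csv(out / "control_zscores.csv")
    if (out / "subtype_labels.csv").exists():
        state.subtype_labels = pd.read_csv(out / "subtype_labels.csv")
    return state
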