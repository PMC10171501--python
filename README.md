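# dfcsubtype

Unsupervised subtype discovery for first-episode drug-naive major
depression (FEDN-MDD) from resting-state dynamic functional connectivity.
The package implements, as a tested and reusable pipeline, an analysis in
which whole-brain sliding-window connectivity is decomposed into guided
independent components, each patient is scored against an age-referenced
normative model of healthy variation, and patients are partitioned into
subtypes by stability-driven clustering on the most informative deviation
features. Because the clinical data this style of analysis targets are
request-only, the package also ships a synthetic cohort generator with
ground truth at every stage, so every estimator can be validated by
planted-structure recovery.

It is intended for methods researchers in neuroimaging-based patient
stratification: the library modules are importable building blocks, the
numbered scripts under `analysis/` are a worked end-to-end study, and the
pipeline can also be driven from the shell.

## The analysis

For each subject with ROI time series `X ∈ R^{T×m}` (AAL-style, m = 90;
TR = 2 s, T ≥ 210):

1. **Dynamic FC** — sliding-window Pearson correlations (window 60 s, step
   1 volume), Fisher-transformed and vectorised over the E = m(m−1)/2
   edges: a `W×E` matrix per subject.
2. **Guided ICA** — group ICA (PCA reduction + FastICA, K = 20) on an
   independent healthy sample yields reference connectivity components;
   each subject's components are back-reconstructed anchored to these
   references, with per-window component weights by OLS.
3. **Features** — per component: the global efficiency of the weighted
   graph of its loadings, `E_glob = (1/(m(m−1))) Σ_{i≠j} 1/d_ij`, and the
   fluctuation coefficient `mean_t |w_{t+1} − w_t|` of its weight
   trajectory → 40 features per subject.
4. **Normative deviations** — per feature, second-order polynomial
   quantile curves (5th/50th/95th) fit on healthy controls and aggregated
   over 10 folds; each patient scores
   `z = (C_real − C_50th) / (C_95th − C_5th)` at their age, averaged over
   folds.
5. **Subtype discovery** — 100-run wrapper forward selection (k-means,
   silhouette criterion, permutation-calibrated stopping) marks features
   selected in >80% of runs as informative; 100 aligned k-means runs on
   those features give each patient a label and a certainty
   `max_i n_i / n`; low-certainty patients are excluded post hoc.
6. **Inference** — covariate-adjusted (age/sex/education) Freedman–Lane
   permutation t-tests (n = 5000, two-sided, p < .01 per feature) contrast
   controls and subtypes.

`docs/methods.md` derives each step, states all defaults, and documents
the generator and the known resolution limits.

## Worked example

The numbered scripts reproduce the full study on a reduced-scale synthetic
cohort (m = 30 ROIs, 91 patients with planted 16%/84% subtypes, 91 matched
controls, 125 ICA controls):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_connectivity_decomposition.py
python analysis/03_features_normative.py
python analysis/04_subtype_discovery.py
python analysis/05_group_inference.py
```

The run shipped in `results/` printed:

```
decomposition: {'n_windows': 181, 'n_edges': 435,
  'reference_similarity_mean': 0.921, ...}
scored 91 patients on 40 features; median |z| 0.242, max |z| 2.93
subtype discovery: {'cluster_sizes': {'II': 76, 'I': 15},
  'silhouette': 0.492, 'mean_stability': 1.0,
  'n_excluded_low_certainty': 0, 'ari_vs_planted': 1.0, ...}
control_vs_subtype_I: 19 significant features of 40
control_vs_subtype_II: 3 significant features of 40
subtype_I_vs_subtype_II: 19 significant features of 40
illness duration I vs II: p = 0.292
```

Read: the pipeline recovers the planted 15/76 split exactly (adjusted Rand
index 1.0 against the generator's labels), every patient keeps the same
label across all 100 clustering runs (stability 1.0), and the severe
subtype I deviates from controls on far more features than the mild
subtype II — the heterogeneity pattern the method is designed to expose.

The same pipeline runs from the shell (`dfcsubtype simulate`, `dfcsubtype
run`, or stage-by-stage `qc`/`match`/`dfc`/`ica`/…) or from Python:

```python
import dfcsubtype as d

gt = d.generate_ground_truth(k_true=20, m=30, seed=11)
manifest, series = d.generate_cohort(gt, seed=11)
state = d.run_full_pipeline(d.PipelineConfig(seed=11), manifest, series)
print(state.selection.informative_features)
print(state.subtype_labels.head())
```

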