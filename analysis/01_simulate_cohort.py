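#!/usr/bin/env python
"""Generate the synthetic study cohort.

Builds a reduced-scale stand-in for the restricted clinical dataset: 91
first-episode drug-naive patients with two planted subtypes (16% / 84%,
deviation shifts on 12 of 40 features), 91 healthy-base controls, and 125
healthy-ICA controls; 30-ROI BOLD-like series of 210 volumes at TR = 2 s.
Writes the manifest and ground truth under scratch/cohort/ for the
downstream analysis steps and a cohort summary under results/.
"""

from pathlib import Path

import dfcsubtype as d
from dfcsubtype.io import save_json, write_manifest, write_timeseries
from dfcsubtype.synthetic import save_ground_truth

SEED = 11
OUT = Path("scratch/cohort")
RESULTS = Path("results")


def main():
    gt = d.generate_ground_truth(k_true=20, m=30, seed=SEED)
    manifest, series = d.generate_cohort(
        gt, n_patients=91, n_controls_base=91, n_controls_ica=125,
        t_volumes=210, tr=2.0, seed=SEED,
    )
    OUT.mkdir(parents=True, exist_ok=True)
    write_manifest(manifest, OUT / "manifest.csv")
    (OUT / "tr.txt").write_text("2.0")
    for ts in series:
        write_timeseries(ts, OUT / "series" / f"{ts.subject_id}.tsv")
    save_ground_truth(gt, OUT / "ground_truth.npz")

    counts = manifest.query("group == 'patient'")["subtype_true"].value_counts()
    summary = {
        "seed": SEED,
        "n_subjects": len(manifest),
        "groups": manifest["group"].value_counts().to_dict(),
        "planted_subtypes": counts.to_dict(),
        "age_mean": float(manifest["age"].mean()),
        "n_rois": gt.n_rois,
        "n_components_true": gt.n_components,
    }
    save_json(summary, RESULTS / "cohort_summary.json")
    print("cohort generated:", summary)


if __name__ == "__main__":
    main()
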