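#!/usr/bin/env python
"""Network features and age-referenced normative deviation scores.

Extracts the 40 per-subject features (20 global-efficiency measures and 20
fluctuation coefficients), fits the 10-fold polynomial quantile normative
model on the healthy-base controls, and scores every patient's deviation
z-vector. Feature and z tables are copied under results/.
"""

from pathlib import Path

from dfcsubtype.pipeline import load_state, run_full_pipeline

STATE = Path("scratch/pipeline")
RESULTS = Path("results")


def main():
    state = load_state(STATE)
    state = run_full_pipeline(
        state.config, state.manifest, {}, out_dir=STATE,
        stages=["features", "normative"], state=state,
    )
    RESULTS.mkdir(exist_ok=True)
    # compact rounded copies; full precision stays under scratch/pipeline/
    state.zscores.round(4).to_csv(RESULTS / "zscores.csv", index=False)
    state.control_zscores.round(4).to_csv(RESULTS / "control_zscores.csv", index=False)
    z = state.zscores.iloc[:, 1:]
    print(
        f"scored {len(state.zscores)} patients on {z.shape[1]} features; "
        f"median |z| {z.abs().median().median():.3f}, "
        f"max |z| {z.abs().max().max():.2f}"
    )


if __name__ == "__main__":
    main()
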