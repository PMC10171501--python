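#!/usr/bin/env python
"""Covariate-adjusted permutation contrasts between groups.

Compares the deviation features of healthy-base controls and the two
patient subtypes (5000 permutations, age/sex/education as covariates,
p < .01 per feature) and tests the illness-duration difference between
subtypes. Contrast tables are copied under results/.
"""

import shutil
from pathlib import Path

from dfcsubtype.pipeline import load_state, run_full_pipeline

STATE = Path("scratch/pipeline")
RESULTS = Path("results")


def main():
    state = load_state(STATE)
    state = run_full_pipeline(
        state.config, state.manifest, {}, out_dir=STATE, stages=["stats"], state=state
    )
    for name, table in state.stats.items():
        shutil.copy(STATE / f"stats_{name}.csv", RESULTS / f"stats_{name}.csv")
        n_sig = int(table["significant"].sum()) if "significant" in table else 0
        print(f"{name}: {n_sig} significant features of {len(table)}")
    dur = state.stats.get("duration_I_vs_II")
    if dur is not None:
        print(f"illness duration I vs II: p = {float(dur['p_perm'].iloc[0]):.3f}")


if __name__ == "__main__":
    main()
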