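#!/usr/bin/env python
"""3D immunofluorescence quantification on a phantom cohort.

Generates four groups of two-channel confocal phantoms with true
chromosome/cytoplasm intensity ratios 3.0, 2.0, 1.2 and 1.0 (the last is
the secondary-only control), runs the median-filter / Otsu / shell pipeline
on every cell, and compares each group to the control with Welch t-tests.
Writes results/if_measurements.tsv and results/if_group_comparison.tsv.
"""

from pathlib import Path

import pandas as pd

from fibermod.image_quant import compare_groups, quantify_stack, simulate_cells

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main():
    RESULTS.mkdir(exist_ok=True)
    specs = [dict(group=name, true_ratio=r, cytoplasm_level=200.0,
                  noise_sd=0.10, n_cells=10)
             for name, r in (("strong", 3.0), ("moderate", 2.0),
                             ("weak", 1.2), ("control", 1.0))]
    cells, truth = simulate_cells(specs, seed=1)
    meas = [quantify_stack(c["dapi"], c["signal"], c["cell_id"], c["group"])
            for c in cells]
    pd.DataFrame([m.__dict__ for m in meas]).to_csv(
        RESULTS / "if_measurements.tsv", sep="\t", index=False)

    groups = compare_groups(meas, "control")
    groups.to_csv(RESULTS / "if_group_comparison.tsv", sep="\t", index=False)
    merged = groups.merge(
        truth.groupby("group").true_ratio.first().rename("true_ratio"),
        on="group")
    print(merged[["group", "n", "true_ratio", "mean_ratio", "t",
                  "p"]].to_string(index=False))
    sig = merged[(merged.group != "control") & (merged.p < 1e-10)]
    print(f"\ngroups separating from control at p < 1e-10: "
          f"{', '.join(sig.group)}")


if __name__ == "__main__":
    main()
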