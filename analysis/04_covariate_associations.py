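#!/usr/bin/env python
"""Associate irreversibility with cognition and regional volume, per group:
Pearson correlations with BH correction per family. By construction of the
generator the cognitive association should appear in the AD group only and
the volume association in HC only; this driver measures whether the
estimated irreversibility (not the hidden κ) recovers that structure.

Writes results/associations/associations.tsv.
"""

from pathlib import Path

import pandas as pd

from braintime.io import read_cohort
from braintime.stats import correlate_with_fdr

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "associations"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    results = pd.read_csv(ROOT / "compute" / "irreversibility.tsv", sep="\t")
    cohort = read_cohort(ROOT / "cohort" / "cohort.csv")
    volumes = pd.read_csv(ROOT / "cohort" / "volumes.csv").set_index("subject_id")

    g = results[results["level"] == "global"].merge(cohort, on="subject_id")
    g["mean_volume"] = volumes.mean(axis=1).loc[g["subject_id"]].to_numpy()

    rows = []
    for group in ("HC", "AD"):
        sub = g[g["group"] == group]
        out = correlate_with_fdr(
            sub[["I"]].assign(I2=sub["I"]),
            sub[["cognitive_score", "mean_volume"]],
            [("I", "cognitive_score"), ("I2", "mean_volume")],
        )
        out.insert(0, "group", group)
        out["x"] = "global_I"
        rows.append(out)
    table = pd.concat(rows, ignore_index=True)
    table.to_csv(OUT / "associations.tsv", sep="\t", index=False)
    print(table.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
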