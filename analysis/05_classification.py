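#!/usr/bin/env python
"""Classify HC vs AD with a random forest under repeated stratified 5-fold
cross-validation (50 repeats), comparing feature sets: irreversibility
(global + nodal I) vs the cohort's cognitive score vs their combination.

Writes results/classification/metrics.json.
"""

import json
from pathlib import Path

import pandas as pd

from braintime.classify import FeatureTable, crossval_rf
from braintime.io import read_cohort
from braintime.pipeline import feature_table_from_results

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "classification"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    results = pd.read_csv(ROOT / "compute" / "irreversibility.tsv", sep="\t")
    cohort = read_cohort(ROOT / "cohort" / "cohort.csv")

    irr = feature_table_from_results(results, cohort, levels=("global", "node"))
    cog = FeatureTable(
        cohort.set_index("subject_id")[["cognitive_score"]].loc[irr.features.index],
        irr.labels,
    )
    combined = FeatureTable(
        irr.features.join(cog.features), irr.labels,
    )

    payload = {}
    for name, table in (("irreversibility", irr), ("cognition", cog),
                        ("combined", combined)):
        cv = crossval_rf(table, folds=5, repeats=50, seed=SEED)
        payload[name] = {"mean": cv.mean.to_dict(), "sd": cv.sd.to_dict()}
        print(f"{name:16s} AUC {cv.mean['auc']:.3f} ± {cv.sd['auc']:.3f}  "
              f"accuracy {cv.mean['accuracy']:.3f}")
    (OUT / "metrics.json").write_text(json.dumps(payload, indent=2) + "\n")


if __name__ == "__main__":
    main()
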