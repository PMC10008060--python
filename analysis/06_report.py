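#!/usr/bin/env python
"""Assemble the markdown summary of all completed stages into
results/report.md."""

import json
from pathlib import Path

import pandas as pd

from braintime.pipeline import run_report

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    comp_path = ROOT / "compare" / "group_comparison.tsv"
    comp = pd.read_csv(comp_path, sep="\t") if comp_path.exists() else None
    cv_path = ROOT / "classification" / "metrics.json"
    cv_summary = None
    if cv_path.exists():
        payload = json.loads(cv_path.read_text())["irreversibility"]
        cv_summary = pd.DataFrame({"mean": payload["mean"], "sd": payload["sd"]})
    text = run_report(comparisons=comp, cv_summary=cv_summary)
    (ROOT / "report.md").write_text(text + "\n")
    print(f"report -> {ROOT/'report.md'}")


if __name__ == "__main__":
    main()
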