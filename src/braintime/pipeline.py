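"""End-to-end orchestration: simulate → compute → compare → classify → report.

Every run is driven by a serializable `RunConfig`; the resolved config is
written next to the outputs so any result table can be regenerated
bit-for-bit from (config, seed, inputs).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core, io, stats, synth
from .classify import FeatureTable, crossval_rf

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved parameters of one analysis run (JSON round-trippable)."""

    modality: str = "fmri"
    sampling_interval: float = 2.6
    window_length: int = 20
    hop: int = 1
    shift: int = 1
    partition_path: str | None = None
    alpha: float = 0.05
    fdr: bool = True
    mad_k: float = 3.0
    covariates: tuple[str, ...] = ("age", "education")
    folds: int = 5
    repeats: int = 50
    n_trees: int = 100
    seed: int = 0

    def window_spec(self) -> io.WindowSpec:
        return io.WindowSpec(length=self.window_length, hop=self.hop, shift=self.shift)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = dataclasses.asdict(self)
        payload["covariates"] = list(self.covariates)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        payload["covariates"] = tuple(payload.get("covariates", ("age", "education")))
        return cls(**payload)


def results_to_frame(results: list[core.IrreversibilityResult]) -> pd.DataFrame:
    """Tidy per-subject table: one row per (subject, level) with I and
    variability columns; levels are 'global', 'node:<label>', 'network:<name>'."""
    rows = []
    for r in results:
        rows.append({
            "subject_id": r.subject_id, "level": "global", "I": r.global_I,
            "variability_temporal": r.variability_temporal,
            "variability_spatial": r.variability_spatial,
        })
        for label, v in zip(r.region_labels, r.nodal):
            rows.append({"subject_id": r.subject_id, "level": f"node:{label}",
                         "I": float(v), "variability_temporal": np.nan,
                         "variability_spatial": np.nan})
        for net, v in r.per_network.items():
            rows.append({"subject_id": r.subject_id, "level": f"network:{net}",
                         "I": v, "variability_temporal": np.nan,
                         "variability_spatial": np.nan})
    return pd.DataFrame(rows)


def run_compute(
    config: RunConfig,
    input_dir: str | Path,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Compute per-subject irreversibility for every series file in a directory.

    Unreadable subjects are skipped with a logged reason; the run fails if
    more than 20% of subjects are skipped. Writes ``irreversibility.tsv``,
    a JSON mirror and the resolved config when ``out_dir`` is given.
    """
    input_dir = Path(input_dir)
    paths = sorted(list(input_dir.glob("*.tsv")) + list(input_dir.glob("*.csv")))
    if not paths:
        raise FileNotFoundError(f"no series files (*.tsv, *.csv) in {input_dir}")
    partition = io.load_partition(config.partition_path) if config.partition_path else None
    spec = config.window_spec()
    results, skipped = [], 0
    for path in paths:
        try:
            series = io.read_series(
                path, modality=config.modality,
                sampling_interval=config.sampling_interval,
            )
            res = core.subject_irreversibility(series, spec, partition)
        except (ValueError, io.SeriesFormatError) as exc:
            logger.warning("skipping %s: %s", path.name, exc)
            skipped += 1
            continue
        logger.info("subject %s: %d windows, %d dropped, shift %d",
                    res.subject_id, len(res.per_window_I) + res.n_windows_dropped,
                    res.n_windows_dropped, spec.shift)
        results.append(res)
    if skipped > 0.2 * len(paths):
        raise RuntimeError(f"{skipped}/{len(paths)} subjects unreadable; aborting")
    frame = results_to_frame(results)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out_dir / "irreversibility.tsv", sep="\t", index=False)
        frame.to_json(out_dir / "irreversibility.json", orient="records", indent=2)
        config.to_json(out_dir / "config.json")
    return frame


def run_compare(
    config: RunConfig,
    results: pd.DataFrame,
    cohort: pd.DataFrame,
    adjust_covariates: bool = False,
) -> pd.DataFrame:
    """Group comparisons (HC vs AD) at every computed level.

    The global row compares global I and both variability readings; nodal
    rows form one BH family (all nodes), network rows another — matching
    correction "across brain regions" within one modality/band. MAD-based
    exclusion runs per feature before testing. With ``adjust_covariates``
    the feature is first replaced by its OLS residuals on the configured
    covariates.
    """
    merged = results.merge(cohort, on="subject_id")
    for grp in ("HC", "AD"):
        if (merged.loc[merged["level"] == "global", "group"] == grp).sum() < 3:
            raise ValueError(f"fewer than 3 {grp} subjects after merge")
    mad_k = config.mad_k

    def _one(level_df: pd.DataFrame, column: str, feature: str) -> stats.GroupComparison:
        vals = level_df[column].to_numpy(dtype=float)
        grps = level_df["group"].to_numpy()
        if adjust_covariates:
            cov = level_df[list(config.covariates)]
            vals = stats.covariate_adjust(vals, cov)
        return stats.compare_groups(vals, grps, feature, mad_k=mad_k)

    rows: list[stats.GroupComparison] = []
    g = merged[merged["level"] == "global"]
    global_family = [
        _one(g, "I", "global"),
        _one(g, "variability_temporal", "variability_temporal"),
        _one(g, "variability_spatial", "variability_spatial"),
    ]
    stats.adjust_family(global_family)
    rows.extend(global_family)

    node_levels = sorted(
        l for l in merged["level"].unique() if l.startswith("node:"))
    node_family = [_one(merged[merged["level"] == l], "I", l) for l in node_levels]
    stats.adjust_family(node_family)
    rows.extend(node_family)

    net_levels = sorted(
        l for l in merged["level"].unique() if l.startswith("network:"))
    net_family = [_one(merged[merged["level"] == l], "I", l) for l in net_levels]
    stats.adjust_family(net_family)
    rows.extend(net_family)

    return pd.DataFrame([dataclasses.asdict(c) for c in rows])


def feature_table_from_results(
    results: pd.DataFrame, cohort: pd.DataFrame, levels: tuple[str, ...] = ("global", "node"),
) -> FeatureTable:
    """Pivot per-subject irreversibility rows into a classifier feature table."""
    keep = results["level"] == "__none__"
    if "global" in levels:
        keep |= results["level"] == "global"
    if "node" in levels:
        keep |= results["level"].str.startswith("node:")
    if "network" in levels:
        keep |= results["level"].str.startswith("network:")
    wide = results[keep].pivot(index="subject_id", columns="level", values="I")
    labels = cohort.set_index("subject_id").loc[wide.index, "group"]
    return FeatureTable(wide, labels)


def run_classify(
    config: RunConfig,
    results: pd.DataFrame,
    cohort: pd.DataFrame,
    levels: tuple[str, ...] = ("global", "node"),
):
    """Random-forest CV on irreversibility features; returns a `CVResult`."""
    table = feature_table_from_results(results, cohort, levels)
    return crossval_rf(table, folds=config.folds, repeats=config.repeats,
                       seed=config.seed, n_trees=config.n_trees)


def run_report(
    comparisons: pd.DataFrame | None = None,
    cv_summary: pd.DataFrame | None = None,
    group_means: pd.DataFrame | None = None,
) -> str:
    """Assemble a human-readable markdown summary of completed stages.

    Missing stages are noted, never fatal; an empty comparison table yields
    a report with zero rows.
    """
    lines = ["# Irreversibility analysis report", ""]
    if group_means is not None:
        lines += ["## Group means", "", group_means.to_markdown(), ""]
    if comparisons is None:
        lines += ["## Group comparisons", "", "_stage not run_", ""]
    else:
        lines += ["## Group comparisons (rank-sum, BH-FDR, Cohen's d)", ""]
        if len(comparisons):
            lines += [comparisons.to_markdown(index=False), ""]
        else:
            lines += ["no comparisons computed", ""]
    if cv_summary is None:
        lines += ["## Classification", "", "_stage not run_", ""]
    else:
        lines += ["## Classification (stratified 5-fold CV, mean ± SD over repeats)",
                  "", cv_summary.to_markdown(), ""]
    return "\n".join(lines)


def write_cohort(cohort: synth.SyntheticCohort, out_dir: str | Path) -> None:
    """Write a synthetic cohort in the layout `run_compute` reads: one TSV per
    subject, cohort.csv, truth.json and regional volumes."""
    out_dir = Path(out_dir)
    series_dir = out_dir / "series"
    series_dir.mkdir(parents=True, exist_ok=True)
    for s in cohort.series:
        io.write_series(s, series_dir / f"{s.subject_id}.tsv")
    cohort.cohort.to_csv(out_dir / "cohort.csv", index=False)
    (out_dir / "truth.json").write_text(json.dumps(cohort.truth, indent=2) + "\n")
    if cohort.volumes is not None:
        cohort.volumes.to_csv(out_dir / "volumes.csv")
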