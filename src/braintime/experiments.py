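"""Self-contained validation experiments for the irreversibility pipeline.

Each function regenerates its inputs from a seed, runs the relevant part of
the package, and returns measured quantities: demographic-table statistics
recomputed from published summaries, closed-form and simulation oracles for
the estimator, statistical calibration, and classifier sanity checks. The
analysis drivers and the acceptance script both build on these.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import core, synth
from .classify import FeatureTable, classification_metrics, crossval_rf
from .io import WindowSpec
from .stats import (
    SummaryStats,
    adjust_family,
    anova_f_from_summary,
    bh_fdr,
    chi2_2x2,
    compare_groups,
)

#: Published cohort demographics (mean, SD, n per group) and sex counts for
#: the three in-study samples and the out-of-sample validation cohort.
DEMOGRAPHICS = {
    "fmri": {
        "age": (SummaryStats(69.92, 7.89, 65), SummaryStats(76.85, 7.46, 42)),
        "sex": [[41, 24], [26, 16]],
    },
    "eeg": {
        "age": (SummaryStats(72.16, 6.70, 25), SummaryStats(76.53, 7.61, 28)),
        "sex": [[15, 10], [17, 11]],
    },
    "matched": {
        "age": (SummaryStats(71.86, 6.94, 22), SummaryStats(76.18, 7.70, 22)),
        "sex": [[13, 9], [13, 9]],
    },
    "adni": {
        "age": (SummaryStats(72.75, 8.51, 115), SummaryStats(73.62, 7.95, 91)),
        "sex": [[59, 56], [38, 53]],
    },
}


def table_statistics() -> dict[str, float]:
    """Recompute the demographic-table test statistics from the published
    per-group summaries: one-way ANOVA F for age, Pearson χ² for sex."""
    out: dict[str, float] = {}
    for sample, spec in DEMOGRAPHICS.items():
        F, _ = anova_f_from_summary(*spec["age"])
        chi2, _ = chi2_2x2(spec["sex"])
        out[f"anova_f_age_{sample}"] = F
        out[f"chi2_sex_{sample}"] = chi2
    return out


def reversal_identity_error(seed: int, n_pairs: int = 100, length: int = 500) -> float:
    """Max deviation between the explicit-flip reversal correlation and the
    forward correlation at negative lag (direct-summation oracle)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_pairs):
        x = rng.normal(size=length)
        y = rng.normal(size=length)
        shift = int(rng.integers(1, 25))
        lhs = core.lagged_corr(core.reverse(x), core.reverse(y), shift)
        # oracle: correlate x(t) with y(t - shift) over the aligned overlap
        a = x[shift:] - x[shift:].mean()
        b = y[: length - shift] - y[: length - shift].mean()
        rhs = float((a @ b) / np.sqrt((a @ a) * (b @ b)))
        worst = max(worst, abs(lhs - rhs))
    return worst


def sinusoid_grid_max_error() -> float:
    """Max |measured - closed form| of pairwise irreversibility over a 5×5
    (phase, shift) grid; closed form 2|sin(ωΔ)·sin(φ)|."""
    omega = 2 * np.pi / 64
    worst = 0.0
    for phi in (0.0, np.pi / 8, np.pi / 4, 3 * np.pi / 8, np.pi / 2):
        s = synth.make_sinusoid_pair(omega, phi, 6400)
        for shift in (4, 8, 12, 16, 20):
            got = core.pairwise_irreversibility(s.data[0], s.data[1], shift)
            expected = 2 * abs(np.sin(omega * shift) * np.sin(phi))
            worst = max(worst, abs(got - expected))
    return worst


def _whole_series_I(kappa: float, n: int, T: int, seed: int) -> float:
    model = synth.make_var_model(n, kappa, seed=seed)
    series = synth.simulate_var(model, T, seed=seed + 10_000)
    I, _ = core.global_irreversibility(core.fs_matrices(series.data, 1))
    return I


def detailed_balance_ratio(seed: int, n_seeds: int = 20, n: int = 10,
                           T: int = 5000) -> float:
    """Mean global I of reversible (κ=0) runs over mean of maximally
    irreversible (κ=1) runs; ≪ 1 when the estimator respects detailed balance."""
    i0 = [_whole_series_I(0.0, n, T, seed + k) for k in range(n_seeds)]
    i1 = [_whole_series_I(1.0, n, T, seed + k) for k in range(n_seeds)]
    return float(np.mean(i0) / np.mean(i1))


def kappa_monotonicity(seed: int, n_seeds: int = 20, n: int = 10,
                       T: int = 2000) -> list[float]:
    """Median global I per asymmetry level κ ∈ {0, .25, .5, .75, 1}."""
    medians = []
    for j, kappa in enumerate((0.0, 0.25, 0.5, 0.75, 1.0)):
        vals = [_whole_series_I(kappa, n, T, seed + 1000 * j + k)
                for k in range(n_seeds)]
        medians.append(float(np.median(vals)))
    return medians


def _cohort_global_I(cohort: synth.SyntheticCohort, spec: WindowSpec
                     ) -> tuple[list[float], list[float]]:
    groups = dict(zip(cohort.cohort["subject_id"], cohort.cohort["group"]))
    by_group: dict[str, list[float]] = {"HC": [], "AD": []}
    for s in cohort.series:
        res = core.subject_irreversibility(s, spec)
        by_group[groups[s.subject_id]].append(res.global_I)
    return by_group["HC"], by_group["AD"]


def window_robustness(seed: int, lengths: tuple[int, ...] = (20, 30, 40, 50)
                      ) -> dict[int, float]:
    """HC vs AD separation across window lengths: BH-adjusted rank-sum p of
    the global-I contrast on a default synthetic cohort, per window length."""
    cohort = synth.make_cohort(seed=seed)
    comps = []
    for length in lengths:
        hc, ad = _cohort_global_I(cohort, WindowSpec(length, hop=1, shift=1))
        comps.append(compare_groups(np.concatenate([hc, ad]),
                                    np.array(["HC"] * len(hc) + ["AD"] * len(ad)),
                                    feature=str(length)))
    adjust_family(comps)
    return {int(c.feature): c.p_adj for c in comps}


def type_i_error(seed: int, n_replicates: int = 200) -> float:
    """Rejection fraction of the compare pipeline's global test on null
    cohorts (equal κ in both groups, α = 0.05 after BH)."""
    spec = WindowSpec(20, hop=4, shift=1)
    rejections = 0
    for rep in range(n_replicates):
        cohort = synth.make_cohort(n_hc=10, n_ad=10, n_regions=10, T=200,
                                   kappa_hc=0.5, kappa_ad=0.5,
                                   seed=seed + rep)
        groups = dict(zip(cohort.cohort["subject_id"], cohort.cohort["group"]))
        feats = {"I": [], "vt": [], "vs": []}
        labels = []
        for s in cohort.series:
            res = core.subject_irreversibility(s, spec)
            feats["I"].append(res.global_I)
            feats["vt"].append(res.variability_temporal)
            feats["vs"].append(res.variability_spatial)
            labels.append(groups[s.subject_id])
        labels_arr = np.array(labels)
        family = [compare_groups(np.array(feats[k]), labels_arr, k)
                  for k in ("I", "vt", "vs")]
        adjust_family(family)
        rejections += family[0].p_adj < 0.05
    return rejections / n_replicates


def bh_worked_example() -> list[float]:
    return [float(v) for v in bh_fdr([0.01, 0.02, 0.03, 0.04])]


def _irreversibility_features(cohort: synth.SyntheticCohort, spec: WindowSpec
                              ) -> FeatureTable:
    rows = {}
    for s in cohort.series:
        res = core.subject_irreversibility(s, spec)
        rows[s.subject_id] = np.concatenate([[res.global_I], res.nodal])
    feats = pd.DataFrame.from_dict(rows, orient="index")
    feats.columns = ["global"] + [f"node_{i}" for i in range(feats.shape[1] - 1)]
    groups = cohort.cohort.set_index("subject_id")["group"]
    return FeatureTable(feats, groups.loc[feats.index])


def classifier_checks(seed: int, repeats: int = 50) -> dict[str, float]:
    """Separable-cohort AUC, permuted-label AUC, and the max deviation of
    score-based AUC from its Mann-Whitney normalization."""
    cohort = synth.make_cohort(n_hc=30, n_ad=30, n_regions=20, T=300,
                               kappa_hc=0.8, kappa_ad=0.2, seed=seed)
    table = _irreversibility_features(cohort, WindowSpec(20, hop=2, shift=1))
    cv = crossval_rf(table, repeats=repeats, seed=seed)
    # chance-level null: fresh label permutation per block of repeats, so the
    # mean AUC averages over permutation draws rather than tracking one
    rng = np.random.default_rng(seed + 1)
    n_perms = 5
    perm_aucs = []
    for p in range(n_perms):
        permuted = FeatureTable(
            table.features,
            pd.Series(rng.permutation(table.labels.to_numpy()),
                      index=table.labels.index),
        )
        cv_p = crossval_rf(permuted, repeats=max(repeats // n_perms, 1),
                           seed=seed + 2 + p)
        perm_aucs.append(cv_p.mean["auc"])
    auc_permuted = float(np.mean(perm_aucs))

    from scipy.stats import mannwhitneyu

    worst = 0.0
    for k in range(10):
        r = np.random.default_rng(seed + 100 + k)
        y = np.array([0] * 15 + [1] * 15)
        scores = r.normal(size=30) + 0.5 * y
        m = classification_metrics(1, 1, 1, 1, scores=scores, y_true=y)
        u = mannwhitneyu(scores[y == 1], scores[y == 0]).statistic
        worst = max(worst, abs(m["auc"] - u / 225.0))
    return {
        "auc_separable": float(cv.mean["auc"]),
        "auc_permuted": auc_permuted,
        "accuracy_separable": float(cv.mean["accuracy"]),
        "auc_mannwhitney_max_error": worst,
    }


def exact_identities(seed: int) -> dict[str, float]:
    """Deviations of the algebraic identities (all must be exactly zero):
    mean(nodal) vs global, I at shift 0, all-regions network vs global."""
    rng = np.random.default_rng(seed)
    w = rng.normal(size=(8, 150)).cumsum(axis=1) * 0.05 + rng.normal(size=(8, 150))
    fs = core.fs_matrices(w, 2)
    I, _ = core.global_irreversibility(fs)
    nodal_dev = abs(float(np.mean(core.nodal_irreversibility(fs))) - I)
    fs0 = core.fs_matrices(w, 0)
    I0, _ = core.global_irreversibility(fs0)
    from .io import NetworkPartition

    labels = [f"r{i}" for i in range(8)]
    part = NetworkPartition({l: "whole" for l in labels})
    nets = core.network_irreversibility(w, 2, part, labels)
    return {
        "mean_nodal_minus_global": nodal_dev,
        "I_at_shift_zero": abs(I0),
        "all_regions_network_minus_global": abs(nets["whole"] - I),
    }
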