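# braintime

Temporal-irreversibility ("arrow of time") analysis of parcellated brain
signals, built for studying how neurodegeneration shifts large-scale brain
dynamics toward thermodynamic equilibrium. The package targets
researchers working with resting-state fMRI or source-space EEG region ×
time matrices who want a tested, reproducible pipeline for estimating
irreversibility at the global, nodal and network levels, comparing
patient and control groups, relating irreversibility to covariates, and
classifying subjects — plus a synthetic-cohort generator with ground-truth
nonequilibrium strength, so every stage is verifiable without access to
patient recordings.

## The measure

A stationary process obeying detailed balance is statistically
indistinguishable from its time reversal; departures from equilibrium make
the forward and reversed signals distinguishable. For regions *i, j* and
lag Δt, the time-shifted Pearson correlation r = ⟨xᵢ(t), xⱼ(t+Δt)⟩ is
mapped to a functional dependency

    FS_ij(Δt) = −½ · ln(1 − r²)

computed once on the forward series (FS_forward) and once on the
time-reversed series (FS_reversal). The level of irreversibility is their
quadratic distance:

    FSdiff_ij = (FS_forward,ij − FS_reversal,ij)²
    I    = mean_ij FSdiff_ij        (global)
    I_i  = (1/n) Σ_j FSdiff_ij      (nodal)

and the same mean restricted to one resting-state network's member regions
gives the network-level value. Estimation runs in sliding windows
(20 samples, hop 1 for fMRI-scale data); a subject's global I is the
across-window mean and the across-window SD is the temporal variability of
irreversibility. For EEG-band analysis the lag is chosen per band from the
decay of the signal autocorrelation (δ 15, θ 7, α 5, β 3, γ 2 samples).

Synthetic cohorts come from a stationary VAR(1), x(t+1) = A·x(t) + ε(t)
with A ∝ S + κ·K (S symmetric, K antisymmetric): κ = 0 satisfies detailed
balance exactly, and κ ∈ (0, 1] dials in genuine irreversibility, giving
every generated subject a known nonequilibrium strength. Patients ("AD")
are drawn at lower κ than controls ("HC").

## Worked example

The numbered drivers under `analysis/` run the full study on a synthetic
cohort (20 HC + 20 AD, 30 regions, 300 samples at TR 2.6 s, κ 0.8 vs 0.3),
writing tables under `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_compute_irreversibility.py
python analysis/03_group_comparison.py
python analysis/04_covariate_associations.py
python analysis/05_classification.py
python analysis/06_report.py
```

Output of the comparison stage:

```
global I: p_adj=6.24e-07, d=3.95 (after age/education adjustment: p_adj=8.19e-04)
30/30 nodes significant after FDR
          feature  p_adj      d
 network:anterior    0.0 3.3261
network:posterior    0.0 2.9519
```

Patients' dynamics sit measurably closer to equilibrium: the global
contrast survives rank-sum testing with BH correction (p_adj ≈ 6·10⁻⁷) at
a very large effect size (Cohen's d ≈ 4), at every node, in both synthetic
networks, and after regressing out the age/education confound built into
the cohort. The classification stage (random forest, stratified 5-fold ×
50 repeats) prints

```
irreversibility  AUC 0.994 ± 0.002  accuracy 0.967
cognition        AUC 1.000 ± 0.004  accuracy 0.975
combined         AUC 0.998 ± 0.002  accuracy 0.973
```

i.e. irreversibility features alone carry nearly all the discriminative
signal of this strongly contrasted cohort.

The same machinery is importable directly:

```python
import braintime as bt

series = bt.read_series("subject01.tsv", sampling_interval=2.6)
result = bt.subject_irreversibility(series, bt.WindowSpec(length=20, hop=1, shift=1))
print(result.global_I, result.variability_temporal)
```

A `braintime` console script exposes the same stages
(`simulate` / `compute` / `compare` / `classify` / `report`) for shell use.

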