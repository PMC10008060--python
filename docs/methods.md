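# Methods

## Irreversibility estimator

The estimator detects the arrow of time in a multivariate stationary
signal by comparing forward and time-reversed evolution through lagged
correlations. For a window X (n regions × L samples) and shift Δt, every
ordered pair (i, j) — the diagonal included — contributes

    r_forward  = corr(x_i(t), x_j(t+Δt)),   t = 0 … L−Δt−1
    r_reversal = the same on the time-flipped window

each mapped to FS = −½·ln(1 − r²) (natural log; the mutual information of
a bivariate Gaussian with correlation r). The irreversibility readouts are
built from FSdiff_ij = (FS_forward,ij − FS_reversal,ij)²:

* global I — mean over all n² elements;
* nodal I_i — row means of FSdiff;
* network I — the same mean restricted to a network's member rows/columns
  (pairwise entries do not depend on regions outside the pair, so the
  restriction is a submatrix; networks need ≥ 2 member regions);
* spatial SD — population SD of the FSdiff elements.

Windowing: half-open windows [k·hop, k·hop + length), trailing partial
windows discarded. A subject's global I is the across-window mean of
windowed I; the across-window SD (population, ddof 0) is the *temporal*
variability; the across-window mean of the element SD is the *spatial*
variability. Both variability readings are computed and reported because
either can be meant by "variability of irreversibility"; the temporal one
is the per-subject headline.

Key identities, enforced exactly rather than approximately: global I is
computed as the mean of the nodal vector (bit-identical to the element
mean); at Δt = 0 the forward and reversal correlations run over identical
sample pairs, so the reversal matrix is set equal to the forward matrix
and I = 0 exactly; restricting a partition to all regions reproduces the
global value bit for bit.

### Defaults and parameters

| parameter | default | rationale |
|---|---|---|
| window length (fMRI) | 20 samples | balances sensitivity/specificity for dynamic correlation changes |
| window length (EEG) | 2 s of samples | chosen here; kHz-scale rates need an explicit scale |
| hop | 1 sample (T ≤ 1000), else window length | preserves sliding semantics where cheap, bounds cost on EEG-rate data |
| shift Δt | fMRI 1 TR; EEG broadband 2; δ/θ/α/β/γ = 15/7/5/3/2 samples | per-band autocorrelation decay; `select_shift` recomputes it as the first lag where the region-averaged autocorrelation drops below 1/e (capped at length/4) |
| FS clamp | r² ≤ 1 − 10⁻¹² | keeps entries finite (≈ 13.8 at |r| = 1) without affecting |r| ≤ 0.999999 |
| Butterworth order | 4, forward–backward | zero phase (effective order 8); phase matters for a temporal-asymmetry measure |
| coherence | Welch, 1 s Hann segments, 50% overlap | standard single-taper estimate |

Degenerate inputs: a correlation over a constant segment is flagged (NaN),
never silently zeroed; a window with more than 1% flagged FS entries is
dropped from all subject averages and counted. Correlations are plain
Pearson on the truncated overlap — no extra detrending beyond upstream
filtering.

## Synthetic cohorts

The generator is a discrete-time VAR(1), x(t+1) = A·x(t) + ε(t) with
isotropic Gaussian noise and A = s·(S + κ·K), S random symmetric, K random
antisymmetric, rescaled to spectral radius 0.9 (strong temporal dependence
without near-unit-root behavior). With κ = 0 the process satisfies
detailed balance exactly — an analytic reversible null — and κ ∈ (0, 1]
introduces solenoidal flux, i.e. true irreversibility. A discrete-time
model was preferred over a continuous Ornstein–Uhlenbeck surrogate
because it matches sampled data directly and has a discrete Lyapunov
equation (P = A·P·Aᵀ + Σ) as an independent oracle for its second moments.
EEG-like cohorts reuse the same generator with post-hoc band-pass
filtering; linear filtering preserves the driving asymmetry.

Cohort structure (defaults): 20 HC + 20 AD subjects, 30 regions, 300
samples at TR 2.6 s. Per-subject κ ~ Normal(group mean, 0.1) truncated to
[0, 1], group means 0.8 (HC) vs 0.3 (AD). Covariates emulate an
AD-vs-control demographic table: age HC ~ N(70, 7.9) / AD ~ N(77, 7.5)
years; education N(14.9, 3) / N(10.5, 3) years; sex F with probability
0.63 in both groups. The cognitive score is flat around 26 points in HC
and 10 + 12·κ + N(0, 2) in AD (lower asymmetry ⇒ worse cognition, an
association present in patients only); per-region volumes are
45 + 8·κ + N(0, 2) in HC and flat in AD (volume association in controls
only). These choices give the pipeline realistic effect directions while
keeping every association's ground truth known.

What the generator does *not* emulate: hemodynamic convolution,
measurement noise spectra, head motion, spatial autocorrelation of real
parcellations, site effects, or nonlinear neural dynamics. Passing tests
therefore demonstrate that the estimator and statistics recover known
asymmetry structure from linear stationary surrogates — not that any
particular clinical effect size is expected in real recordings.

## Statistics

Group contrasts use the two-sided Wilcoxon rank-sum test (exact p when the
smaller group has ≤ 8 observations and no ties; tie-corrected normal
approximation otherwise), Benjamini–Hochberg FDR within each family (the
three global features; all nodes; all networks — correction is applied
across regions within one modality/band, not pooled across bands), and
Cohen's d with the pooled SD. Outliers beyond 3 scaled MADs
(1.4826·median absolute deviation) from the median are excluded per
feature before testing; a zero MAD keeps everything with a warning.
Demographic confounds are handled by replacing the feature with its OLS
residuals on intercept + age + education (configurable) before testing.
χ² for 2×2 tables is Pearson's without continuity correction — required to
match published two-decimal statistics — and two-group ANOVA F values are
recomputed from published (mean, SD, n) summaries via F = t² of the
pooled-variance t-test. w-scores fit the normative regression on controls
only (the pooled-fit alternative is ambiguous in common usage) and divide
residuals by the normative residual SD.

Note that BH adjustment is *not* idempotent on its own output (e.g.
[0.1, 0.9] → [0.2, 0.9] → [0.4, 0.9]); the tested guarantees are
monotonicity in rank order, p_adj ≥ p, and the cap at 1.

## Classification

Features (global + nodal I by default, extensible with FC, cognition,
volumes) feed a random forest — 100 trees, unlimited depth, √(#features)
candidate splits — under stratified 5-fold cross-validation repeated 50
times with seeded fold assignment. Missing cells are imputed by weighted
KNN (k = 5, inverse-distance weights, Euclidean distance on mutually
observed standardized features) fitted inside each training fold and
applied to its test fold, avoiding leakage. Out-of-fold vote fractions
are pooled per repeat for the ROC (stable at n ≈ 50); threshold metrics
(precision, sensitivity, specificity, accuracy, F1) use a 0.5 vote
threshold, with undefined ratios reported as missing rather than zero.

## Validation experiments and problem sizes

`braintime.experiments` regenerates every validation quantity from a seed:

* published demographic tables — F and χ² recomputed from printed
  summaries (the fMRI-sample age F lands at 20.533 against a printed
  20.51; the difference is entirely the two-decimal rounding of the
  printed means and SDs);
* reversal identity — 100 random pairs, L = 500, against a
  direct-summation negative-lag oracle (agreement to ~10⁻¹⁶);
* closed-form sinusoid fixture — 5×5 (φ, Δ) grid against 2|sin(ωΔ)sin(φ)|;
* detailed-balance null — κ=0 vs κ=1, n=10 regions, T=5000, 20 seeds per
  level (ratio ~10⁻³); κ-monotonicity on a 5-level grid at T=2000;
* window robustness — default cohort, window lengths 20/30/40/50, hop 1;
* type-I calibration — 200 null cohorts (κ=0.5 both groups, 10+10
  subjects, 10 regions, T=200, window 20, hop 4), rejection of the
  BH-adjusted global test at α=0.05;
* classifier checks — 30+30 cohort at κ 0.8 vs 0.2, 20 regions; the
  permuted-label null averages over five fresh permutations.

Sizes were fixed once to keep each experiment well-powered yet quick on a
single CPU; medians over seeds are used wherever a single draw would be
noisy.

## Known limitations

The FS mapping assumes approximately Gaussian marginals for its
mutual-information reading; heavy-tailed signals shift absolute values
though not the forward/reversal comparison. Finite windows leave a
positive bias in I even for reversible processes (it vanishes as window
length grows — the tested null compares against a matched irreversible
level rather than zero). The VAR surrogate cannot probe nonlinear or
nonstationary irreversibility mechanisms. Coherence uses a single Hann
taper; multitaper estimates would lower variance for short EEG epochs.
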