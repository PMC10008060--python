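"""Synthetic cohorts with controllable temporal irreversibility.

The generator is a stationary first-order vector autoregression

    x(t+1) = A·x(t) + ε(t),   ε ~ N(0, σ²·Id),

whose coupling matrix is split into symmetric and antisymmetric parts,
A ∝ S + κ·K. With isotropic noise and κ = 0 (symmetric A) the process
satisfies detailed balance and is exactly time-reversible; the asymmetry
parameter κ ∈ [0, 1] dials in solenoidal probability flux and hence
temporal irreversibility, giving every subject a ground-truth
"nonequilibrium strength". Cohorts emulate a healthy-control (HC) versus
Alzheimer's-type (AD) contrast in which patients carry lower κ, a
cognitive score that tracks κ inside the patient group only, and regional
volumes that track κ in controls only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ParcellatedSeries


@dataclass
class VARModel:
    """A stationary VAR(1) with tagged coupling asymmetry."""

    n: int
    A: np.ndarray
    noise_sd: float
    kappa: float
    spectral_radius: float

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (self.n, self.n):
            raise ValueError("A must be n × n")
        if self.spectral_radius >= 1.0:
            raise ValueError("model is non-stationary (spectral radius >= 1)")

    def stationary_cov(self, tol: float = 1e-14, max_iter: int = 100_000) -> np.ndarray:
        """Stationary covariance P solving P = A·P·Aᵀ + σ²·Id by iteration."""
        P = np.eye(self.n) * self.noise_sd**2
        for _ in range(max_iter):
            P_next = self.A @ P @ self.A.T + np.eye(self.n) * self.noise_sd**2
            if np.max(np.abs(P_next - P)) < tol:
                return P_next
            P = P_next
        return P


@dataclass
class EffectParams:
    """Group/covariate structure of a generated cohort.

    Cognitive score (MoCA-like, points): flat around ``cog_mean_hc`` in HC,
    ``cog_intercept_ad + cog_slope_ad·κ`` plus noise in AD (positive slope:
    less irreversible dynamics, worse cognition). Regional volume
    (arbitrary units): ``vol_base + vol_slope_hc·κ`` plus noise per region
    in HC, flat in AD — mirroring a volume association present in controls
    only.
    """

    cog_mean_hc: float = 26.0
    cog_intercept_ad: float = 10.0
    cog_slope_ad: float = 12.0
    cog_noise_sd: float = 2.0
    vol_base: float = 45.0
    vol_slope_hc: float = 8.0
    vol_noise_sd: float = 2.0
    age_mean: dict = field(default_factory=lambda: {"HC": 70.0, "AD": 77.0})
    age_sd: dict = field(default_factory=lambda: {"HC": 7.9, "AD": 7.5})
    edu_mean: dict = field(default_factory=lambda: {"HC": 14.9, "AD": 10.5})
    edu_sd: dict = field(default_factory=lambda: {"HC": 3.0, "AD": 3.0})
    female_fraction: float = 0.63


@dataclass
class SyntheticCohort:
    """Generated series + cohort table + per-subject ground-truth κ."""

    series: list[ParcellatedSeries]
    cohort: pd.DataFrame
    truth: dict[str, float]
    volumes: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        groups = set(self.cohort["group"])
        if not {"HC", "AD"} <= groups:
            raise ValueError("cohort must contain both HC and AD groups")


def make_var_model(
    n: int,
    kappa: float,
    coupling_scale: float = 0.9,
    seed: int | np.random.Generator = 0,
) -> VARModel:
    """Random VAR(1) with coupling A = s·(S + κ·K), rescaled to the target
    spectral radius (default 0.9: strong temporal dependence, safely inside
    the unit circle).

    S is a random symmetric matrix, K a random antisymmetric matrix, both
    drawn from the seeded generator; κ = 0 gives A = Aᵀ exactly.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not 0.0 <= kappa <= 1.0:
        raise ValueError("kappa must lie in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    G = rng.normal(size=(n, n))
    H = rng.normal(size=(n, n))
    S = (G + G.T) / 2.0
    K = (H - H.T) / 2.0
    M = S + kappa * K
    rho = float(np.max(np.abs(np.linalg.eigvals(M))))
    A = (coupling_scale / rho) * M
    return VARModel(n=n, A=A, noise_sd=1.0, kappa=kappa, spectral_radius=coupling_scale)


def simulate_var(
    model: VARModel,
    T: int,
    burn_in: int = 200,
    sampling_interval: float = 2.6,
    seed: int | np.random.Generator = 0,
    *,
    subject_id: str = "subject",
    modality: str = "fmri",
) -> ParcellatedSeries:
    """Simulate ``T`` post-burn-in samples of the model.

    The chain starts at the origin; ``burn_in`` initial samples are
    discarded so the retained stretch is effectively stationary. Regions
    are labeled region_0 … region_{n-1}.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if burn_in < 100:
        raise ValueError("burn_in must be >= 100")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = model.n
    eps = rng.normal(scale=model.noise_sd, size=(burn_in + T, n))
    X = np.empty((burn_in + T, n))
    x = np.zeros(n)
    A = model.A
    for t in range(burn_in + T):
        x = A @ x + eps[t]
        X[t] = x
    return ParcellatedSeries(
        subject_id=subject_id,
        modality=modality,
        sampling_interval=sampling_interval,
        region_labels=[f"region_{i}" for i in range(n)],
        data=X[burn_in:].T.copy(),
    )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def make_cohort(
    n_hc: int = 20,
    n_ad: int = 20,
    n_regions: int = 30,
    T: int = 300,
    kappa_hc: float = 0.8,
    kappa_ad: float = 0.3,
    kappa_sd: float = 0.1,
    effect_params: EffectParams | None = None,
    seed: int = 0,
    sampling_interval: float = 2.6,
    burn_in: int = 200,
) -> SyntheticCohort:
    """Generate an HC vs AD cohort with ground-truth asymmetry.

    Per-subject κ is drawn from a normal with the group mean, SD
    ``kappa_sd``, truncated to [0, 1]; each subject gets a fresh random
    coupling matrix at its κ. Covariates follow `EffectParams`. The whole
    cohort is bit-reproducible from (parameters, seed).
    """
    if not 0.0 <= kappa_ad <= 1.0 and 0.0 <= kappa_hc <= 1.0:
        raise ValueError("group kappas must lie in [0, 1]")
    if min(n_hc, n_ad) < 3:
        raise ValueError("need at least 3 subjects per group")
    ep = effect_params or EffectParams()
    rng = np.random.default_rng(seed)
    series: list[ParcellatedSeries] = []
    truth: dict[str, float] = {}
    rows = []
    vol_rows = {}
    for group, count, kmean in (("HC", n_hc, kappa_hc), ("AD", n_ad, kappa_ad)):
        kappas = _truncated_normal(rng, kmean, kappa_sd, 0.0, 1.0, count)
        ages = rng.normal(ep.age_mean[group], ep.age_sd[group], size=count)
        edus = np.clip(rng.normal(ep.edu_mean[group], ep.edu_sd[group], size=count), 0, None)
        sexes = np.where(rng.random(count) < ep.female_fraction, "F", "M")
        for i in range(count):
            sid = f"{group.lower()}_{i:03d}"
            kappa = float(kappas[i])
            model = make_var_model(n_regions, kappa, seed=rng)
            s = simulate_var(model, T, burn_in=burn_in,
                             sampling_interval=sampling_interval,
                             seed=rng, subject_id=sid)
            series.append(s)
            truth[sid] = kappa
            if group == "AD":
                cog = ep.cog_intercept_ad + ep.cog_slope_ad * kappa \
                    + rng.normal(scale=ep.cog_noise_sd)
                vols = ep.vol_base + rng.normal(scale=ep.vol_noise_sd, size=n_regions)
            else:
                cog = ep.cog_mean_hc + rng.normal(scale=ep.cog_noise_sd)
                vols = ep.vol_base + ep.vol_slope_hc * kappa \
                    + rng.normal(scale=ep.vol_noise_sd, size=n_regions)
            cog = float(np.clip(cog, 0.0, 30.0))
            rows.append({
                "subject_id": sid, "group": group, "sex": sexes[i],
                "age": float(ages[i]), "education": float(edus[i]),
                "cognitive_score": cog,
            })
            vol_rows[sid] = vols
    cohort = pd.DataFrame(rows)
    volumes = pd.DataFrame.from_dict(
        vol_rows, orient="index",
        columns=[f"region_{i}" for i in range(n_regions)],
    )
    volumes.index.name = "subject_id"
    return SyntheticCohort(series=series, cohort=cohort, truth=truth, volumes=volumes)


def make_sinusoid_pair(
    omega: float,
    phi: float,
    L: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    sampling_interval: float = 1.0,
) -> ParcellatedSeries:
    """Two-region fixture x(t)=sin(ωt)+ε, y(t)=sin(ωt+φ)+ε.

    The pairwise irreversibility of this pair at shift Δ has the closed
    form 2·|sin(ωΔ)·sin(φ)| (noise-free, many periods), used as an
    analytic oracle.
    """
    if L * omega < 2 * np.pi * 20:
        raise ValueError("L must cover at least 20 periods")
    rng = np.random.default_rng(seed)
    t = np.arange(L, dtype=float)
    x = np.sin(omega * t)
    y = np.sin(omega * t + phi)
    if noise_sd > 0:
        x = x + rng.normal(scale=noise_sd, size=L)
        y = y + rng.normal(scale=noise_sd, size=L)
    return ParcellatedSeries(
        subject_id="sinusoid_pair", modality="eeg",
        sampling_interval=sampling_interval,
        region_labels=["x", "y"], data=np.vstack([x, y]),
    )
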