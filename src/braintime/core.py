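"""Temporal-irreversibility (arrow of time) estimation from time-shifted correlations.

The method compares the forward evolution of a multivariate signal with its
time-reversed copy. For each ordered region pair (i, j) and lag Δt, the
time-shifted Pearson correlation r = <x_i(t), x_j(t+Δt)> is mapped to a
mutual-information-style functional dependency

    FS_ij(Δt) = -1/2 · ln(1 - r²),

computed once on the forward series (FS_forward) and once on the
time-reversed series (FS_reversal). A stationary reversible process
(detailed balance) is statistically indistinguishable from its reversal, so
the two matrices coincide in expectation; the level of irreversibility is
their quadratic distance

    FSdiff_ij = (FS_forward,ij - FS_reversal,ij)²,
    I = mean_ij FSdiff_ij          (global),
    I_i = 1/n · Σ_j FSdiff_ij      (nodal),

and the same mean restricted to the member regions of a network gives the
network-level value. Estimation runs in sliding windows; a subject's global
I is the across-window mean, and its across-window SD is the temporal
variability of irreversibility.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import BandSpec, NetworkPartition, ParcellatedSeries, WindowSpec, make_windows

logger = logging.getLogger(__name__)

#: clamp on r² keeping -1/2·ln(1-r²) finite for |r| = 1
FS_EPS = 1e-12

#: a window is dropped when more than this fraction of FS entries is undefined
MAX_FLAGGED_FRACTION = 0.01


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is requested on a constant segment."""


def reverse(x: np.ndarray) -> np.ndarray:
    """Time-reversed copy of a series (flip the time ordering)."""
    return np.asarray(x)[::-1]


def lagged_corr(x: np.ndarray, y: np.ndarray, shift: int) -> float:
    """Pearson correlation of (x(t), y(t+shift)) over t = 0 … L-shift-1.

    Returns NaN (the flagged undefined value) when either overlapped
    segment is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    L = x.size
    if y.size != L:
        raise ValueError("series must have equal length")
    if L <= shift + 2:
        raise ValueError(f"series length {L} too short for shift {shift}")
    a = x[: L - shift] if shift else x
    b = y[shift:] if shift else y
    a = a - a.mean()
    b = b - b.mean()
    na = np.sqrt(a @ a)
    nb = np.sqrt(b @ b)
    if na == 0.0 or nb == 0.0:
        return np.nan
    return float(np.clip((a @ b) / (na * nb), -1.0, 1.0))


def pairwise_irreversibility(x: np.ndarray, y: np.ndarray, shift: int) -> float:
    """|c_forward(Δt) - c_reversal(Δt)| for one pair of series.

    For a phase-shifted sinusoid pair x=sin(ωt), y=sin(ωt+φ) this equals
    2·|sin(ωΔt)·sin(φ)| in the long-series limit, which the tests use as a
    closed-form oracle.
    """
    cf = lagged_corr(x, y, shift)
    cr = lagged_corr(reverse(x), reverse(y), shift)
    return abs(cf - cr)


def fs_entry(r: float) -> float:
    """Map a correlation to its functional-dependency value -1/2·ln(1-r²).

    NaN (flagged undefined correlation) propagates; |r| > 1 is rejected.
    r² is clamped to 1 - 1e-12, capping the entry near 13.8.
    """
    if np.isnan(r):
        return np.nan
    if abs(r) > 1.0:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    return -0.5 * float(np.log1p(-min(r * r, 1.0 - FS_EPS)))


@dataclass
class FSMatrices:
    """Forward and reversal functional-dependency matrices at one shift."""

    shift: int
    forward: np.ndarray
    reversal: np.ndarray

    def __post_init__(self) -> None:
        self.forward = np.asarray(self.forward, dtype=float)
        self.reversal = np.asarray(self.reversal, dtype=float)
        if self.forward.shape != self.reversal.shape:
            raise ValueError("forward/reversal shape mismatch")
        for m in (self.forward, self.reversal):
            valid = m[~np.isnan(m)]
            if valid.size and (valid < 0).any():
                raise ValueError("FS entries must be nonnegative")

    @property
    def diff(self) -> np.ndarray:
        """FSdiff: element-wise squared forward-reversal difference."""
        return (self.forward - self.reversal) ** 2

    @property
    def n_flagged(self) -> int:
        return int(np.isnan(self.forward).sum() + np.isnan(self.reversal).sum())


def _corr_matrix(X: np.ndarray, shift: int) -> np.ndarray:
    """All-pairs time-shifted correlation: C[i,j] = corr(x_i(t), x_j(t+shift)).

    Rows with a constant overlapped segment yield NaN in their row/column.
    """
    L = X.shape[1]
    A = X[:, : L - shift] if shift else X
    B = X[:, shift:] if shift else X
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    na = np.sqrt(np.einsum("ij,ij->i", A, A))
    nb = np.sqrt(np.einsum("ij,ij->i", B, B))
    with np.errstate(invalid="ignore", divide="ignore"):
        C = (A @ B.T) / np.outer(na, nb)
    C[np.outer(na == 0, np.ones_like(nb, dtype=bool))] = np.nan
    C[np.outer(np.ones_like(na, dtype=bool), nb == 0)] = np.nan
    return np.clip(C, -1.0, 1.0)


def _fs_of(C: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        r2 = np.minimum(C * C, 1.0 - FS_EPS)
        return -0.5 * np.log1p(-r2)


def fs_matrices(window: np.ndarray, shift: int) -> FSMatrices:
    """Forward and reversal FS matrices of one region × length window.

    All n² ordered pairs, diagonal included (the diagonal compares a
    signal's autocorrelation with that of its reversal and is ≈ 0 up to edge
    effects). At shift 0 the reversal matrix equals the forward matrix
    identically — the correlations run over the same sample pairs — so it is
    taken equal without recomputation, making I = 0 exact.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2:
        raise ValueError("window must be 2-D (regions × samples)")
    L = window.shape[1]
    if L <= shift + 2:
        raise ValueError(f"window length {L} too short for shift {shift}")
    forward = _fs_of(_corr_matrix(window, shift))
    if shift == 0:
        reversal = forward.copy()
    else:
        reversal = _fs_of(_corr_matrix(window[:, ::-1], shift))
    return FSMatrices(shift=shift, forward=forward, reversal=reversal)


def _mean_and_sd(diff_sub: np.ndarray) -> tuple[float, float]:
    """Mean/SD of FSdiff elements; the mean is taken as the mean of row
    means so that mean(nodal) == global holds exactly in floating point."""
    nodal = np.nanmean(diff_sub, axis=1)
    return float(np.mean(nodal)), float(np.nanstd(diff_sub))


def global_irreversibility(fs: FSMatrices) -> tuple[float, float]:
    """Global level of irreversibility and spatial SD of FSdiff.

    Returns ``(I, spatial_sd)`` where I is the mean over all n² FSdiff
    elements and spatial_sd their population SD. Flagged (NaN) entries are
    excluded from both; callers enforce the dropped-window policy.
    """
    return _mean_and_sd(fs.diff)


def nodal_irreversibility(fs: FSMatrices) -> np.ndarray:
    """Nodal irreversibility vector: I_i = (1/n)·Σ_j FSdiff[i, j]."""
    return np.nanmean(fs.diff, axis=1)


def network_irreversibility(
    window: np.ndarray,
    shift: int,
    partition: NetworkPartition,
    labels: list[str],
) -> dict[str, float]:
    """Global-style irreversibility restricted to each network's regions.

    Pairwise FS entries do not depend on regions outside the pair, so the
    restriction is the member-row/column submatrix of the full FSdiff; with
    all regions in one network this reproduces the global value bit for bit.
    Networks with fewer than 2 member regions are omitted with a warning.
    """
    fs = fs_matrices(window, shift)
    return network_irreversibility_from_fs(fs, partition, labels)


def network_irreversibility_from_fs(
    fs: FSMatrices, partition: NetworkPartition, labels: list[str]
) -> dict[str, float]:
    out: dict[str, float] = {}
    diff = fs.diff
    for network in partition.networks:
        idx = partition.members(network, labels)
        if len(idx) < 2:
            warnings.warn(
                f"network {network!r} has {len(idx)} member region(s); omitted",
                stacklevel=2,
            )
            continue
        out[network], _ = _mean_and_sd(diff[np.ix_(idx, idx)])
    return out


@dataclass
class IrreversibilityResult:
    """Per-subject irreversibility summary across sliding windows."""

    subject_id: str
    global_I: float
    variability_temporal: float  # SD of windowed I across windows
    variability_spatial: float   # mean across windows of the FSdiff element SD
    nodal: np.ndarray
    per_network: dict[str, float] = field(default_factory=dict)
    per_window_I: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_windows_dropped: int = 0
    region_labels: list[str] = field(default_factory=list)


def subject_irreversibility(
    series: ParcellatedSeries,
    spec: WindowSpec,
    partition: NetworkPartition | None = None,
) -> IrreversibilityResult:
    """Windowed irreversibility pipeline for one subject.

    Each window yields FS matrices at ``spec.shift``; windows where more
    than 1% of FS entries are undefined (constant segments) are dropped from
    all averages and counted. The subject's global I is the across-window
    mean of windowed I, its temporal variability the across-window SD
    (population), nodal and network values are across-window means.
    """
    windows = make_windows(series, spec)
    per_I: list[float] = []
    per_sd: list[float] = []
    nodal_acc: list[np.ndarray] = []
    net_acc: dict[str, list[float]] = {}
    dropped = 0
    n = series.n_regions
    for w in windows:
        fs = fs_matrices(w, spec.shift)
        if fs.n_flagged > MAX_FLAGGED_FRACTION * 2 * n * n:
            dropped += 1
            continue
        nodal = nodal_irreversibility(fs)
        per_I.append(float(np.mean(nodal)))
        per_sd.append(float(np.nanstd(fs.diff)))
        nodal_acc.append(nodal)
        if partition is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                nets = network_irreversibility_from_fs(fs, partition, series.region_labels)
            for k, v in nets.items():
                net_acc.setdefault(k, []).append(v)
    if not per_I:
        raise ValueError(
            f"subject {series.subject_id}: all {len(windows)} windows dropped"
        )
    if dropped:
        logger.info("subject %s: dropped %d/%d windows with flagged entries",
                    series.subject_id, dropped, len(windows))
    per_I_arr = np.array(per_I)
    return IrreversibilityResult(
        subject_id=series.subject_id,
        global_I=float(np.mean(per_I_arr)),
        variability_temporal=float(np.std(per_I_arr)),
        variability_spatial=float(np.mean(per_sd)),
        nodal=np.mean(nodal_acc, axis=0),
        per_network={k: float(np.mean(v)) for k, v in net_acc.items()},
        per_window_I=per_I_arr,
        n_windows_dropped=dropped,
        region_labels=list(series.region_labels),
    )


def select_shift(
    series: ParcellatedSeries,
    threshold: float = float(np.exp(-1)),
    max_lag: int | None = None,
) -> int:
    """Shift selection from the decay of the region-averaged autocorrelation.

    Returns the smallest positive lag at which the autocorrelation function,
    averaged across regions, falls below ``threshold`` (default 1/e), capped
    at length/4 (with a warning when the cap binds).
    """
    T = series.n_samples
    if T < 100:
        raise ValueError("need at least 100 samples for shift selection")
    cap = max_lag if max_lag is not None else T // 4
    X = series.data - series.data.mean(axis=1, keepdims=True)
    denom = np.einsum("ij,ij->i", X, X)
    if np.any(denom == 0):
        warnings.warn("constant region in shift selection; cap returned")
        return cap
    for lag in range(1, cap + 1):
        r = np.einsum("ij,ij->i", X[:, :-lag], X[:, lag:]) / denom
        if r.mean() < threshold:
            return lag
    warnings.warn(
        f"autocorrelation never fell below {threshold:.3f} within {cap} lags; "
        "returning the cap"
    )
    return cap


def fc_pearson(series: ParcellatedSeries) -> np.ndarray:
    """Zero-lag Pearson functional connectivity over the full series.

    Symmetric with unit diagonal; constant regions yield NaN rows/columns.
    """
    if series.n_samples < 3:
        raise ValueError("need at least 3 samples")
    sd = series.data.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(series.data)
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 1.0)
    C[sd == 0, :] = np.nan
    C[:, sd == 0] = np.nan
    return C


def mean_fc(fc: np.ndarray) -> float:
    """Mean of the upper-triangle off-diagonal FC entries."""
    iu = np.triu_indices_from(fc, k=1)
    return float(np.nanmean(fc[iu]))


def fc_coherence(
    series: ParcellatedSeries,
    band: BandSpec,
    segment_seconds: float = 1.0,
) -> np.ndarray:
    """Band-averaged magnitude-squared coherence between all region pairs.

    Welch estimate with Hann-tapered segments of ``segment_seconds`` and 50%
    overlap; in-band frequency bins are averaged. Entries lie in [0, 1];
    diagonal is 1.
    """
    fs_hz = series.sampling_rate
    nperseg = int(round(segment_seconds * fs_hz))
    nperseg = max(min(nperseg, series.n_samples // 4), 8)
    freqs = np.fft.rfftfreq(nperseg, d=series.sampling_interval)
    band_mask = (freqs >= band.low) & (freqs <= band.high)
    if not band_mask.any():
        raise ValueError(
            f"band {band.name} ({band.low}-{band.high} Hz) has no resolvable "
            f"frequency bins at segment length {nperseg}"
        )
    n = series.n_regions
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            _, coh = sps.coherence(
                series.data[i], series.data[j], fs=fs_hz,
                nperseg=nperseg, noverlap=nperseg // 2, window="hann",
            )
            out[i, j] = out[j, i] = float(coh[band_mask].mean())
    return out
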