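"""Reading, validating, filtering, windowing and partitioning parcellated signals.

All on-disk conventions live here: delimited region × time matrices (one row
per region, first column the region label), network partition files
(two-column TSV or a JSON object), cohort tables (CSV), and optional NIfTI
volume + integer-label atlas input for parcellation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal


class SeriesFormatError(ValueError):
    """Raised when an on-disk series violates the expected layout."""


class PartitionError(ValueError):
    """Raised when a region→network partition is inconsistent."""


@dataclass
class ParcellatedSeries:
    """One subject's parcellated recording: a region × time matrix.

    Parameters
    ----------
    subject_id : str
        Identifier carried through all downstream tables.
    modality : {"fmri", "eeg"}
        Recording modality; selects defaults elsewhere (shift, window).
    sampling_interval : float
        Seconds per sample (the TR for fMRI, 1/rate for EEG).
    region_labels : list of str
        Ordered, unique region names; length defines the number of regions.
    data : ndarray, shape (n_regions, n_samples)
        The signal matrix, regions along axis 0.
    """

    subject_id: str
    modality: str
    sampling_interval: float
    region_labels: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.modality not in ("fmri", "eeg"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D region × time matrix")
        n = len(self.region_labels)
        if n < 2:
            raise ValueError("need at least 2 regions")
        if self.data.shape[0] != n:
            raise ValueError(
                f"label count {n} does not match data rows {self.data.shape[0]}"
            )
        if len(set(self.region_labels)) != n:
            dupes = {l for l in self.region_labels if self.region_labels.count(l) > 1}
            raise ValueError(f"duplicate region labels: {sorted(dupes)}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def sampling_rate(self) -> float:
        """Samples per second."""
        return 1.0 / self.sampling_interval

    def with_data(self, data: np.ndarray) -> "ParcellatedSeries":
        """Copy of this series with ``data`` replaced (same metadata)."""
        return ParcellatedSeries(
            self.subject_id, self.modality, self.sampling_interval,
            list(self.region_labels), data,
        )


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with its default correlation shift (samples)."""

    name: str
    low: float
    high: float
    default_shift: int

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError("need 0 < low < high")
        if self.default_shift < 1:
            raise ValueError("default_shift must be >= 1")


#: Canonical EEG bands with their per-band correlation shifts (samples at
#: 512 Hz), chosen from the decay of the signal autocorrelation: slower bands
#: decorrelate later so carry longer shifts.
CANONICAL_BANDS: dict[str, BandSpec] = {
    "broadband": BandSpec("broadband", 0.5, 40.0, 2),
    "delta": BandSpec("delta", 0.5, 4.0, 15),
    "theta": BandSpec("theta", 4.0, 8.0, 7),
    "alpha": BandSpec("alpha", 8.0, 12.0, 5),
    "beta": BandSpec("beta", 12.0, 30.0, 3),
    "gamma": BandSpec("gamma", 30.0, 40.0, 2),
}

#: fMRI BOLD drift-removal band (Hz).
FMRI_BAND = (0.01, 0.1)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: window length, hop and correlation shift.

    ``shift`` is the lag Δt of the time-shifted correlation computed inside
    each window; windows are half-open ``[start, start+length)`` starting at
    0, hop, 2·hop, …
    """

    length: int
    hop: int = 1
    shift: int = 1

    def __post_init__(self) -> None:
        if self.length <= 2 * self.shift:
            raise ValueError("window length must exceed 2 * shift")
        if self.hop < 1:
            raise ValueError("hop must be >= 1")
        if self.shift < 0:
            raise ValueError("shift must be >= 0")


def default_window_spec(series: ParcellatedSeries, shift: int | None = None) -> WindowSpec:
    """Modality-aware window defaults.

    fMRI: 20-sample windows, hop 1, shift 1 TR. EEG: 2 s of samples, hop =
    window length (non-overlapping, bounds cost at kHz-scale rates), shift 2.
    Series longer than 1000 samples also fall back to non-overlapping hops.
    """
    if series.modality == "fmri":
        length = 20
    else:
        length = max(int(round(2.0 * series.sampling_rate)), 8)
    hop = 1 if series.n_samples <= 1000 else length
    if shift is None:
        shift = 1 if series.modality == "fmri" else 2
    return WindowSpec(length=length, hop=hop, shift=shift)


SEVEN_RSNS = (
    "visual", "somatosensory", "motor", "limbic",
    "frontoparietal", "default-mode", "salience",
)


@dataclass
class NetworkPartition:
    """Region → resting-state-network assignment.

    Unmapped regions are allowed and are simply excluded from network-level
    analysis; a region may belong to at most one network.
    """

    mapping: dict[str, str] = field(default_factory=dict)

    @property
    def networks(self) -> list[str]:
        seen: list[str] = []
        for net in self.mapping.values():
            if net not in seen:
                seen.append(net)
        return seen

    def members(self, network: str, labels: list[str]) -> list[int]:
        """Indices of ``labels`` that belong to ``network``."""
        return [i for i, l in enumerate(labels) if self.mapping.get(l) == network]


def load_partition(path: str | Path) -> NetworkPartition:
    """Load a region→network partition from two-column TSV or a JSON object.

    A region listed under two different networks is an error; an empty file
    yields an empty partition (network analysis then unavailable).
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    text = path.read_text().strip()
    if not text:
        return NetworkPartition({})
    if path.suffix.lower() == ".json" or text.startswith("{"):
        raw = json.loads(text)
        items = list(raw.items())
    else:
        items = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split(",")
            if len(parts) != 2:
                raise PartitionError(f"line {lineno}: expected 2 columns, got {len(parts)}")
            items.append((parts[0].strip(), parts[1].strip()))
    for region, network in items:
        if region in mapping and mapping[region] != network:
            raise PartitionError(
                f"region {region!r} mapped to both {mapping[region]!r} and {network!r}"
            )
        mapping[region] = network
    return NetworkPartition(mapping)


def _parse_matrix(df: pd.DataFrame, path: Path) -> np.ndarray:
    values = df.to_numpy(dtype=object)
    out = np.empty(values.shape, dtype=float)
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            try:
                out[i, j] = float(values[i, j])
            except (TypeError, ValueError):
                raise SeriesFormatError(
                    f"{path}: non-numeric cell at row {i}, column {j}: {values[i, j]!r}"
                ) from None
    return out


def read_series(
    path: str | Path,
    labels: list[str] | None = None,
    *,
    subject_id: str | None = None,
    modality: str = "fmri",
    sampling_interval: float = 2.6,
    orientation: str = "infer",
) -> ParcellatedSeries:
    """Read a delimited region × time matrix.

    The on-disk layout is one row per region with the first column carrying
    the region label (``orientation="regions-rows"``), or its transpose with
    a label header row (``orientation="time-rows"``). With
    ``orientation="infer"`` the label axis is detected: if labels are given
    and exactly one axis matches their count, that axis is regions; otherwise
    the row-label layout is assumed.
    """
    path = Path(path)
    if orientation not in ("infer", "regions-rows", "time-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, header=None, dtype=object)

    def _first_col_labels() -> tuple[list[str], np.ndarray]:
        file_labels = [str(v) for v in df.iloc[:, 0]]
        return file_labels, _parse_matrix(df.iloc[:, 1:], path)

    def _header_labels() -> tuple[list[str], np.ndarray]:
        file_labels = [str(v) for v in df.iloc[0, :]]
        return file_labels, _parse_matrix(df.iloc[1:, :], path).T

    if orientation == "regions-rows":
        file_labels, data = _first_col_labels()
    elif orientation == "time-rows":
        file_labels, data = _header_labels()
    else:
        if labels is not None:
            n = len(labels)
            rows_match = df.shape[0] == n
            cols_match = df.shape[1] == n
            if rows_match and cols_match:
                raise SeriesFormatError(
                    f"{path}: both axes match the {n} labels; pass orientation explicitly"
                )
            if cols_match:
                file_labels, data = _header_labels()
            else:
                file_labels, data = _first_col_labels()
        else:
            # default layout: label strings in the first column
            file_labels, data = _first_col_labels()

    if labels is not None:
        if len(file_labels) == len(labels) and file_labels != list(labels):
            # file may carry its own header tokens; trust the caller's labels
            file_labels = list(labels)
    if len(set(file_labels)) != len(file_labels):
        raise SeriesFormatError(f"{path}: duplicate region labels")
    if data.shape[1] < 3:
        raise SeriesFormatError(f"{path}: need at least 3 time samples, got {data.shape[1]}")
    return ParcellatedSeries(
        subject_id=subject_id or path.stem,
        modality=modality,
        sampling_interval=sampling_interval,
        region_labels=file_labels,
        data=data,
    )


def write_series(series: ParcellatedSeries, path: str | Path) -> None:
    """Write a series in the row-per-region layout that `read_series` reads."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    with open(path, "w") as fh:
        for label, row in zip(series.region_labels, series.data):
            fh.write(label + sep + sep.join(repr(float(v)) for v in row) + "\n")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV (subject_id, group, sex, age, education, cognitive_score)."""
    df = pd.read_csv(path)
    required = {"subject_id", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id in cohort table")
    return df


def parcellate(
    volume,
    atlas,
    label_table: list[tuple[int, str]],
    *,
    subject_id: str = "subject",
    modality: str = "fmri",
    sampling_interval: float = 2.6,
) -> ParcellatedSeries:
    """Average a 4-D volume over atlas regions into a region × time matrix.

    ``volume`` and ``atlas`` may be NIfTI file paths, nibabel images, or bare
    arrays (x, y, z, t) and (x, y, z). Each region's time course is the
    arithmetic mean over voxels whose atlas id maps to it; region order
    follows ``label_table``. A region with zero voxels is an error.
    """
    vol = _as_array(volume, ndim=4)
    atl = _as_array(atlas, ndim=3)
    if vol.shape[:3] != atl.shape:
        raise ValueError(f"volume grid {vol.shape[:3]} != atlas grid {atl.shape}")
    atl = np.rint(atl).astype(int)
    rows, labels = [], []
    empty = []
    for region_id, name in label_table:
        mask = atl == region_id
        if not mask.any():
            empty.append(name)
            continue
        rows.append(vol[mask].mean(axis=0))
        labels.append(name)
    if empty:
        raise ValueError(f"atlas regions with zero voxels: {empty}")
    return ParcellatedSeries(subject_id, modality, sampling_interval, labels, np.array(rows))


def _as_array(obj, ndim: int) -> np.ndarray:
    if isinstance(obj, (str, Path)):
        import nibabel as nib

        obj = nib.load(str(obj))
    if hasattr(obj, "get_fdata"):
        obj = obj.get_fdata()
    arr = np.asarray(obj, dtype=float)
    if arr.ndim != ndim:
        raise ValueError(f"expected {ndim}-D array, got {arr.ndim}-D")
    return arr


def bandpass(series: ParcellatedSeries, band: BandSpec, order: int = 4) -> ParcellatedSeries:
    """Zero-phase Butterworth band-pass, applied per region.

    The filter is run forward and backward (`sosfiltfilt`), so an order-4
    design acts with effective order 8 and no phase distortion — phase
    matters here because irreversibility is a temporal-asymmetry measure.
    """
    nyq = series.sampling_rate / 2.0
    if band.high >= nyq:
        raise ValueError(
            f"band high edge {band.high} Hz >= Nyquist {nyq} Hz at "
            f"sampling interval {series.sampling_interval}"
        )
    sos = signal.butter(order, [band.low, band.high], btype="bandpass",
                        fs=series.sampling_rate, output="sos")
    return series.with_data(signal.sosfiltfilt(sos, series.data, axis=1))


def make_windows(series: ParcellatedSeries | np.ndarray, spec: WindowSpec) -> list[np.ndarray]:
    """Sliding windows over time: starts 0, hop, 2·hop, …; trailing partial
    windows are discarded. Returns views (no copies)."""
    data = series.data if isinstance(series, ParcellatedSeries) else np.asarray(series)
    T = data.shape[1]
    if spec.length > T:
        raise ValueError(f"window length {spec.length} exceeds series length {T}")
    n_win = (T - spec.length) // spec.hop + 1
    return [data[:, k * spec.hop: k * spec.hop + spec.length] for k in range(n_win)]
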