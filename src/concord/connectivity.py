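"""Functional connectivity construction from network time series and atlas ROIs.

Network time series are post-processed in a fixed order — per-network
z-scoring, motion regression, linear detrending, de-spiking, 0.01-0.15 Hz
band-pass filtering — before Pearson correlation.  Correlations are
variance-stabilized with the Fisher z (atanh) transform; entries with
|r| = 1 are clipped at atanh(0.999999) and flagged rather than dropped.

ROI-based connectivity averages voxel time series within each atlas region
to a representative series, drops regions that are flat (near-zero variance
and mean) in most subjects, and correlates the retained representatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import median_filter

__all__ = [
    "NetworkTimeseries",
    "FNCMatrix",
    "AtlasDefinition",
    "postprocess_timeseries",
    "compute_fnc",
    "roi_representative_timeseries",
    "roi_exclusion",
    "compute_roi_fc",
    "fnc_to_vector",
    "vector_feature_names",
]

Z_CLIP = np.arctanh(0.999999)


@dataclass
class NetworkTimeseries:
    """K networks x T timepoints, with motion regressors and the TR in seconds."""

    series: np.ndarray
    motion: np.ndarray | None = None
    tr: float = 2.0

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, float)
        if self.series.ndim != 2 or self.series.shape[1] <= 2:
            raise ValueError("series must be K x T with T > 2")
        if not np.all(np.isfinite(self.series)):
            raise ValueError("series must be finite")
        if self.motion is not None:
            self.motion = np.asarray(self.motion, float)
            if self.motion.shape[1] != self.series.shape[1]:
                raise ValueError("motion regressors must match T")

    @property
    def n_networks(self) -> int:
        return self.series.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[1]


@dataclass
class FNCMatrix:
    """Symmetric K x K Fisher-z connectivity matrix; the diagonal is zeroed.

    ``clipped`` marks entries whose correlation was at +/-1 (or a constant
    series) and was clipped to the representable maximum.
    """

    values: np.ndarray
    clipped: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        K = self.values.shape[0]
        if self.values.shape != (K, K):
            raise ValueError("FNC matrix must be square")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("FNC matrix must be symmetric")
        np.fill_diagonal(self.values, 0.0)
        if self.clipped is None:
            self.clipped = np.zeros_like(self.values, dtype=bool)


@dataclass
class AtlasDefinition:
    """Integer label volume with region names and functional-domain tags."""

    labels: np.ndarray
    region_names: list[str]
    domains: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative (0 = background)")
        if len(self.region_names) != int(self.labels.max()):
            raise ValueError("need one region name per positive label")

    @property
    def region_ids(self) -> list[int]:
        return list(range(1, int(self.labels.max()) + 1))


def _despike(x: np.ndarray, window: int = 7, n_mad: float = 4.0) -> np.ndarray:
    """Replace values > n_mad MADs away from a running median.

    The MAD is the series' own robust scale (deviation from its global
    median), so smooth oscillations are left untouched while isolated
    excursions are pulled back to the local median.
    """
    mad = np.median(np.abs(x - np.median(x)))
    if mad == 0:
        return x
    med = median_filter(x, size=window, mode="nearest")
    dev = x - med
    out = x.copy()
    spikes = np.abs(dev) > n_mad * mad
    out[spikes] = med[spikes]
    return out


def postprocess_timeseries(
    ts: NetworkTimeseries, band: tuple[float, float] = (0.01, 0.15)
) -> NetworkTimeseries:
    """Standard FNC post-processing, applied in a fixed order.

    z-score each network's series, regress out the motion regressors,
    remove a linear trend, de-spike (running-median window 7, 4 MAD), and
    band-pass with a 5th-order zero-phase Butterworth filter.  Output series
    are zero-mean per network.
    """
    nyquist = 0.5 / ts.tr
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError("band must satisfy 0 < low < high")
    if hi >= nyquist:
        raise ValueError(f"band upper edge {hi} Hz >= Nyquist {nyquist} Hz")
    X = ts.series.copy()
    # z-score
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd
    # motion regression (with intercept)
    if ts.motion is not None and ts.motion.size:
        R = np.vstack([np.ones(ts.n_timepoints), ts.motion]).T
        beta, *_ = np.linalg.lstsq(R, X.T, rcond=None)
        X = (X.T - R @ beta).T
    # linear detrend
    X = signal.detrend(X, axis=1, type="linear")
    # de-spike
    X = np.vstack([_despike(row) for row in X])
    # band-pass
    sos = signal.butter(5, [lo, hi], btype="bandpass", fs=1.0 / ts.tr, output="sos")
    X = signal.sosfiltfilt(sos, X, axis=1)
    X = X - X.mean(axis=1, keepdims=True)
    return NetworkTimeseries(series=X, motion=ts.motion, tr=ts.tr)


def compute_fnc(ts: NetworkTimeseries) -> FNCMatrix:
    """Pearson correlations between network series, Fisher-z transformed.

    Pairs involving a constant series, and pairs at |r| = 1, are clipped to
    atanh(0.999999) (signed) and flagged in ``clipped``.
    """
    X = ts.series
    sd = X.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    r = np.nan_to_num(r, nan=1.0)  # constant-vs-anything: undefined, flag below
    clipped = (np.abs(r) >= 0.999999) | constant[:, None] | constant[None, :]
    z = np.arctanh(np.clip(r, -0.999999, 0.999999))
    z = np.clip(z, -Z_CLIP, Z_CLIP)
    np.fill_diagonal(z, 0.0)
    np.fill_diagonal(clipped, False)
    z = (z + z.T) / 2
    return FNCMatrix(values=z, clipped=clipped | clipped.T)


def roi_representative_timeseries(
    voxel_data: np.ndarray, atlas: AtlasDefinition, mask: np.ndarray | None = None
) -> tuple[np.ndarray, list[int]]:
    """Unweighted mean voxel series per atlas region.

    ``voxel_data`` is a 4-D (x, y, z, T) array on the atlas grid; ``mask``
    optionally restricts which voxels count.  Returns (regions x T array,
    list of region ids with no in-mask voxels — their rows are NaN).
    """
    data = np.asarray(voxel_data, float)
    if data.ndim != 4:
        raise ValueError("voxel data must be 4-D (x, y, z, time)")
    if data.shape[:3] != atlas.labels.shape:
        raise ValueError("atlas not aligned to data grid")
    sel = np.ones(atlas.labels.shape, bool) if mask is None else np.asarray(mask, bool)
    T = data.shape[3]
    reps = np.full((len(atlas.region_ids), T), np.nan)
    missing: list[int] = []
    for k, rid in enumerate(atlas.region_ids):
        voxels = (atlas.labels == rid) & sel
        if not voxels.any():
            missing.append(rid)
            continue
        reps[k] = data[voxels].mean(axis=0)
    return reps, missing


def roi_exclusion(
    subject_series: list[np.ndarray],
    eps_var: float = 1e-6,
    eps_mean: float = 1e-6,
    subject_fraction: float = 0.9,
) -> np.ndarray:
    """Drop regions that are flat in most subjects.

    A region is excluded when, in more than ``subject_fraction`` of
    subjects, its representative series has variance < ``eps_var`` and
    |mean| < ``eps_mean`` (missing/NaN rows count as flat).  Returns a
    boolean retain mask over regions.
    """
    if not subject_series:
        raise ValueError("no subjects")
    n_regions = subject_series[0].shape[0]
    flat_counts = np.zeros(n_regions)
    for series in subject_series:
        if series.shape[0] != n_regions:
            raise ValueError("inconsistent region count across subjects")
        with np.errstate(invalid="ignore"):
            var = np.nanvar(series, axis=1)
            mean = np.abs(np.nanmean(series, axis=1))
        missing = np.any(np.isnan(series), axis=1)
        flat_counts += ((var < eps_var) & (mean < eps_mean)) | missing
    retain = flat_counts <= subject_fraction * len(subject_series)
    if not retain.any():
        raise ValueError("all regions excluded")
    return retain


def compute_roi_fc(
    series: np.ndarray, retain: np.ndarray | None = None, tr: float = 2.0
) -> FNCMatrix:
    """FC matrix over retained region representative series (Fisher z).

    Mirrors the FNC handling: Pearson correlation then atanh, with |r| = 1
    entries clipped and flagged.
    """
    reps = np.asarray(series, float)
    if retain is not None:
        reps = reps[np.asarray(retain, bool)]
    if reps.shape[0] < 2:
        raise ValueError("need at least 2 retained regions")
    return compute_fnc(NetworkTimeseries(series=reps, tr=tr))


def fnc_to_vector(fnc: FNCMatrix) -> np.ndarray:
    """Upper-triangle edge vector, in the same order as ``vector_feature_names``."""
    iu = np.triu_indices(fnc.values.shape[0], k=1)
    return fnc.values[iu]


def vector_feature_names(n: int, prefix: str = "e") -> list[str]:
    iu = np.triu_indices(n, k=1)
    return [f"{prefix}{i:02d}_{j:02d}" for i, j in zip(*iu)]
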