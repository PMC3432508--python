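"""Resting-state time-series features: regional homogeneity and ROI functional connectivity.

Regional homogeneity (ReHo) measures local temporal synchrony of the BOLD
signal as Kendall's coefficient of concordance (KCC) between a voxel's time
series and those of its cubic neighborhood.  Functional connectivity (FC) is
the Pearson correlation between regional mean time courses.  Both operate on
data that has been linearly detrended and band-pass filtered (0.01-0.08 Hz by
convention for resting-state BOLD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from scipy.stats import rankdata

__all__ = [
    "Volume4D",
    "RehoMap",
    "Parcellation",
    "RoiTimecourses",
    "FcMatrix",
    "detrend_linear",
    "bandpass_filter",
    "kendalls_w",
    "compute_reho_map",
    "smooth_map",
    "extract_roi_timecourses",
    "compute_fc_matrix",
    "prune_fc",
    "vectorize_fc",
    "devectorize_fc",
    "neighborhood_footprint",
]


@dataclass
class Volume4D:
    """A 4D functional volume (x, y, z, t) with acquisition metadata.

    ``mask`` selects brain voxels; every statistic is computed inside it only.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tr: float | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"functional data must be 4D, got {self.data.ndim}D")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 time points")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match spatial shape "
                    f"{self.data.shape[:3]}"
                )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class RehoMap:
    """Per-voxel Kendall's W; NaN marks out-of-mask or undefined voxels."""

    values: np.ndarray
    neighborhood_size: int
    n_timepoints: int


@dataclass
class Parcellation:
    """Integer label volume: 0 is background, positive integers are ROI ids."""

    labels: np.ndarray
    roi_ids: list[int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("parcellation must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.all(self.labels == np.round(self.labels)):
                raise ValueError("parcellation labels must be integers")
            self.labels = self.labels.astype(int)
        if np.any(self.labels < 0):
            raise ValueError("parcellation labels must be nonnegative")
        if self.roi_ids is None:
            self.roi_ids = [int(v) for v in np.unique(self.labels) if v > 0]


@dataclass
class RoiTimecourses:
    """n_timepoints x n_rois matrix of mean regional signals."""

    data: np.ndarray
    roi_ids: list[int] | list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("ROI time courses must be a 2D (time x ROI) matrix")
        if self.roi_ids is None:
            self.roi_ids = list(range(1, self.data.shape[1] + 1))
        if len(self.roi_ids) != self.data.shape[1]:
            raise ValueError("roi_ids length must match number of columns")
        if np.isnan(self.data).any():
            raise ValueError("ROI time courses contain missing values")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class FcMatrix:
    """ROI-by-ROI connectivity: Pearson correlation of regional time courses."""

    values: np.ndarray
    roi_ids: list[int] | list[str] = field(default=None)  # type: ignore[assignment]
    pruned: bool = False
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("FC matrix must be square")
        if self.roi_ids is None:
            self.roi_ids = list(range(1, self.values.shape[0] + 1))

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# temporal preprocessing
# ---------------------------------------------------------------------------


def detrend_linear(ts: np.ndarray, axis: int = 0) -> np.ndarray:
    """Remove the least-squares straight line (intercept + slope) along ``axis``.

    The output has zero mean along ``axis``; a series that is exactly constant
    or exactly linear in time maps to all zeros.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.shape[axis] < 3:
        raise ValueError("detrending requires at least 3 time points")
    return signal.detrend(ts, axis=axis, type="linear")


def bandpass_filter(
    ts: np.ndarray,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    tr: float = 2.0,
    axis: int = 0,
    design: str = "fft",
) -> np.ndarray:
    """Band-pass filter along the time axis, keeping ``low_hz <= f <= high_hz``.

    The reference design (``"fft"``) zeroes DFT bins outside the band,
    including the DC bin; ``"butterworth"`` applies a zero-phase 4th-order
    Butterworth filter instead.
    """
    ts = np.asarray(ts, dtype=float)
    nyquist = 1.0 / (2.0 * tr)
    if not 0 <= low_hz < high_hz:
        raise ValueError(f"invalid band: low {low_hz} must be >= 0 and < high {high_hz}")
    if high_hz >= nyquist:
        raise ValueError(
            f"high cutoff {high_hz} Hz is not below the Nyquist frequency "
            f"{nyquist} Hz for tr={tr}s"
        )
    n = ts.shape[axis]
    if design == "fft":
        freqs = np.fft.rfftfreq(n, d=tr)
        spectrum = np.fft.rfft(ts, axis=axis)
        keep = (freqs >= low_hz) & (freqs <= high_hz)
        shape = [1] * ts.ndim
        shape[axis] = len(freqs)
        spectrum = spectrum * keep.reshape(shape)
        return np.fft.irfft(spectrum, n=n, axis=axis)
    if design == "butterworth":
        sos = signal.butter(
            4, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr, output="sos"
        )
        return signal.sosfiltfilt(sos, ts, axis=axis)
    raise ValueError(f"unknown filter design {design!r}")


# ---------------------------------------------------------------------------
# regional homogeneity (Kendall's coefficient of concordance)
# ---------------------------------------------------------------------------


def neighborhood_footprint(size: int) -> np.ndarray:
    """3x3x3 boolean stencil for the standard cubic neighborhoods.

    27 = full cube, 19 = faces + edges (no corners), 7 = faces only.
    """
    dx, dy, dz = np.meshgrid([-1, 0, 1], [-1, 0, 1], [-1, 0, 1], indexing="ij")
    manhattan = np.abs(dx) + np.abs(dy) + np.abs(dz)
    if size == 27:
        return np.ones((3, 3, 3), dtype=bool)
    if size == 19:
        return manhattan <= 2
    if size == 7:
        return manhattan <= 1
    raise ValueError("neighborhood must be one of 7, 19, 27")


def kendalls_w(series: np.ndarray) -> float:
    """Kendall's coefficient of concordance of K time series of length n.

    Rows are judges (voxels), columns time points.  Each row is ranked over
    time with midranks for ties; with rank sums R_i per time point,

        W = sum(R_i^2) - n * Rbar^2, divided by K^2 (n^3 - n) / 12.

    Returns NaN when every series is constant (concordance undefined).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("expected a K x n matrix of series")
    k, n = series.shape
    if n < 2:
        raise ValueError("need at least 2 time points")
    if np.all(np.ptp(series, axis=1) == 0):
        return float("nan")
    ranks = rankdata(series, axis=1)
    r = ranks.sum(axis=0)
    s = float(np.sum(r**2) - n * r.mean() ** 2)
    return s / (k**2 * (n**3 - n) / 12.0)


def compute_reho_map(
    vol: Volume4D, neighborhood: int = 27, boundary: str = "shrink"
) -> RehoMap:
    """Kendall's W of each in-mask voxel with its cubic neighborhood.

    ``boundary="shrink"`` computes W with the K' <= K neighbors available
    inside the mask (K' replaces K in the normalization); ``boundary="skip"``
    leaves voxels with incomplete neighborhoods as NaN.  Voxels whose whole
    neighborhood is temporally constant are NaN.
    """
    if boundary not in ("shrink", "skip"):
        raise ValueError("boundary must be 'shrink' or 'skip'")
    footprint = neighborhood_footprint(neighborhood)
    data, mask = vol.data, vol.mask
    n = vol.n_timepoints

    ranks = rankdata(data, axis=3)
    ranks = np.where(mask[..., None], ranks, 0.0)

    maskf = mask.astype(float)
    kprime = ndimage.convolve(maskf, footprint.astype(float), mode="constant", cval=0.0)
    kprime = np.round(kprime)

    # Rank sums over the neighborhood, one convolution per time point.
    rbar = kprime * (n + 1) / 2.0  # each rank series sums to n(n+1)/2
    s = np.zeros(data.shape[:3])
    for t in range(n):
        rt = ndimage.convolve(ranks[..., t], footprint.astype(float), mode="constant", cval=0.0)
        s += (rt - rbar) ** 2

    with np.errstate(divide="ignore", invalid="ignore"):
        w = s / (kprime**2 * (n**3 - n) / 12.0)

    values = np.full(data.shape[:3], np.nan)
    values[mask] = np.clip(w[mask], 0.0, 1.0)

    # Undefined where no in-mask neighbor varies over time.
    varying = (np.ptp(data, axis=3) > 0) & mask
    n_varying = ndimage.convolve(
        varying.astype(float), footprint.astype(float), mode="constant", cval=0.0
    )
    values[mask & (np.round(n_varying) == 0)] = np.nan
    if boundary == "skip":
        values[mask & (kprime < neighborhood)] = np.nan
    return RehoMap(values=values, neighborhood_size=neighborhood, n_timepoints=n)


def smooth_map(
    map3d: np.ndarray,
    fwhm_mm: float = 8.0,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Gaussian smoothing with mask-aware kernel renormalization.

    The kernel width is sigma = fwhm / (2 sqrt(2 ln 2)) per axis, in voxel
    units after dividing by the voxel size.  Near mask boundaries the kernel
    is renormalized over the in-mask support, so a constant map stays
    constant.  Out-of-mask voxels are NaN in the output.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm must be positive")
    map3d = np.asarray(map3d, dtype=float)
    if mask is None:
        mask = np.isfinite(map3d)
    if mask.shape != map3d.shape:
        raise ValueError("mask shape must match map shape")
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = [sigma_mm / vs for vs in voxel_size]
    filled = np.where(mask, map3d, 0.0)
    num = ndimage.gaussian_filter(filled, sigma_vox, mode="constant", cval=0.0)
    den = ndimage.gaussian_filter(mask.astype(float), sigma_vox, mode="constant", cval=0.0)
    out = np.full_like(map3d, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        out[mask] = num[mask] / den[mask]
    return out


# ---------------------------------------------------------------------------
# ROI time courses and functional connectivity
# ---------------------------------------------------------------------------


def extract_roi_timecourses(vol: Volume4D, parc: Parcellation) -> RoiTimecourses:
    """Unweighted mean time course over the in-mask voxels of each ROI."""
    if parc.labels.shape != vol.data.shape[:3]:
        raise ValueError("parcellation grid does not match functional grid")
    columns = []
    empty = []
    for roi in parc.roi_ids:
        sel = (parc.labels == roi) & vol.mask
        if not sel.any():
            empty.append(roi)
            continue
        columns.append(vol.data[sel].mean(axis=0))
    if empty:
        raise ValueError(f"ROIs with no in-mask voxels: {empty}")
    return RoiTimecourses(data=np.column_stack(columns), roi_ids=list(parc.roi_ids))


def compute_fc_matrix(ts: RoiTimecourses) -> FcMatrix:
    """Pearson correlation between every pair of ROI time courses.

    Zero-variance columns cannot be correlated; their row and column are NaN
    and a warning is emitted.
    """
    data = ts.data
    variances = data.var(axis=0)
    zero = variances == 0
    if zero.any():
        bad = [ts.roi_ids[i] for i in np.flatnonzero(zero)]
        warnings.warn(
            f"zero-variance ROI time courses, FC undefined for: {bad}",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.corrcoef(data, rowvar=False)
    c = np.asarray(c, dtype=float)
    c = (c + c.T) / 2.0
    valid = ~zero
    c[np.ix_(valid, valid)] = np.clip(c[np.ix_(valid, valid)], -1.0, 1.0)
    c[zero, :] = np.nan
    c[:, zero] = np.nan
    idx = np.flatnonzero(valid)
    c[idx, idx] = 1.0
    return FcMatrix(values=c, roi_ids=list(ts.roi_ids))


def prune_fc(fc: FcMatrix, threshold: float = 0.05) -> FcMatrix:
    """Zero out weak connections with |value| strictly below ``threshold``.

    The diagonal is untouched; entries exactly at the threshold survive.
    Idempotent.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    values = fc.values.copy()
    off = ~np.eye(fc.n_rois, dtype=bool)
    weak = off & (np.abs(values) < threshold) & np.isfinite(values)
    values[weak] = 0.0
    return FcMatrix(
        values=values, roi_ids=list(fc.roi_ids), pruned=True, threshold=threshold
    )


def vectorize_fc(fc: FcMatrix) -> tuple[np.ndarray, list[str]]:
    """Strict upper triangle in row-major order, with ``"i-j"`` feature ids."""
    v = fc.values
    if not np.allclose(v, v.T, equal_nan=True):
        raise ValueError("FC matrix is not symmetric")
    iu, ju = np.triu_indices(fc.n_rois, k=1)
    ids = [f"{fc.roi_ids[i]}-{fc.roi_ids[j]}" for i, j in zip(iu, ju)]
    return v[iu, ju].copy(), ids


def devectorize_fc(
    vec: np.ndarray, roi_ids: list[int] | list[str]
) -> FcMatrix:
    """Inverse of :func:`vectorize_fc`; diagonal restored to 1."""
    m = len(roi_ids)
    vec = np.asarray(vec, dtype=float)
    if vec.size != m * (m - 1) // 2:
        raise ValueError(f"vector length {vec.size} does not match m={m}")
    values = np.eye(m)
    iu, ju = np.triu_indices(m, k=1)
    values[iu, ju] = vec
    values[ju, iu] = vec
    return FcMatrix(values=values, roi_ids=list(roi_ids))
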