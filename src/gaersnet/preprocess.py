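"""Preprocessing of rodent rs-fMRI runs.

Implements the acquisition-to-ROI contract used throughout the package:
selection of a motion-stable epoch, in-plane Gaussian smoothing, hard
Fourier low-pass filtering, ROI mean extraction against an integer label
map, global-signal regression, and temporal-SNR quality assurance.

The fixed processing order is: epoch selection -> smoothing -> low-pass ->
ROI extraction -> global-signal regression.  Regression is applied on the
ROI series rather than voxel-wise; because ROI extraction is a label mean
(linear), the two orders are equivalent and the ROI-level form is directly
testable.  Image realignment/registration is out of scope: the pipeline
expects realigned volumes and a subject-space label map.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "MotionParams",
    "RoiTimeSeries",
    "TsnrResult",
    "select_stable_epoch",
    "lowpass_fourier",
    "regress_global_signal",
    "smooth_image",
    "extract_roi_timeseries",
    "temporal_snr",
]


@dataclass(frozen=True)
class MotionParams:
    """Per-volume rigid-body motion estimates.

    ``translations``: (T, 3) in mm; ``rotations``: (T, 3) in degrees,
    realignment-parameter convention (one row per volume).
    """

    translations: np.ndarray
    rotations: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.translations, dtype=float)
        r = np.asarray(self.rotations, dtype=float)
        if t.ndim != 2 or t.shape[1] != 3 or r.shape != t.shape:
            raise ValueError("expected (T, 3) translations and rotations")
        if not (np.isfinite(t).all() and np.isfinite(r).all()):
            raise ValueError("motion parameters must be finite")
        object.__setattr__(self, "translations", t)
        object.__setattr__(self, "rotations", r)

    @property
    def n_volumes(self) -> int:
        return self.translations.shape[0]


@dataclass(frozen=True)
class RoiTimeSeries:
    """T x R matrix of regional signal time courses.

    ``values``: (T, R) float array, one column per region; ``tr``: sampling
    interval in seconds; ``labels``: unique region abbreviations.
    """

    values: np.ndarray
    tr: float
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        labels = tuple(self.labels)
        if v.ndim != 2:
            raise ValueError("values must be a T x R matrix")
        if v.shape[0] < 2:
            raise ValueError("need at least 2 time points")
        if v.shape[1] != len(labels):
            raise ValueError("label count must match number of columns")
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique")
        if not np.isfinite(v).all():
            raise ValueError("time series must not contain missing values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", labels)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def crop(self, start: int, stop: int) -> "RoiTimeSeries":
        return replace(self, values=self.values[start:stop])


class TsnrResult(float):
    """Mean temporal SNR over mask voxels; carries exclusion bookkeeping."""

    n_voxels: int
    n_zero_sd: int

    def __new__(cls, value: float, n_voxels: int, n_zero_sd: int):
        obj = super().__new__(cls, value)
        obj.n_voxels = n_voxels
        obj.n_zero_sd = n_zero_sd
        return obj


def select_stable_epoch(
    motion: MotionParams,
    epoch_length: int,
    max_translation: float = 0.2,
    max_rotation: float = 0.3,
) -> Optional[tuple[int, int]]:
    """Earliest contiguous window of ``epoch_length`` motion-stable volumes.

    A window qualifies when the peak-to-peak excursion of every translation
    axis stays strictly below ``max_translation`` (mm) and of every rotation
    axis strictly below ``max_rotation`` (degrees).  Returns the half-open
    index interval ``(start, stop)`` of the first qualifying window, so an
    entirely stable run returns its first ``epoch_length`` volumes.  Returns
    ``None`` when no window qualifies (the caller drops the run).
    """
    T = motion.n_volumes
    if epoch_length < 1 or epoch_length > T:
        raise ValueError(f"epoch_length must be in [1, {T}]")
    params = np.hstack([motion.translations, motion.rotations])  # (T, 6)
    windows = np.lib.stride_tricks.sliding_window_view(params, epoch_length, axis=0)
    ptp = windows.max(axis=-1) - windows.min(axis=-1)  # (T - W + 1, 6)
    thresh = np.array([max_translation] * 3 + [max_rotation] * 3)
    ok = (ptp < thresh).all(axis=1)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return None
    start = int(idx[0])
    return (start, start + epoch_length)


def lowpass_fourier(ts: RoiTimeSeries, cutoff: float = 0.1) -> RoiTimeSeries:
    """Hard spectral low-pass: DFT bins strictly above ``cutoff`` Hz zeroed.

    The filter is the literal discrete Fourier mask (no taper); it is linear
    and idempotent and preserves the mean (DC bin) exactly.  The hard mask
    can ring at sharp transients; for the slow BOLD-like signals this
    pipeline targets, that is acceptable.
    """
    nyquist = 0.5 / ts.tr
    if cutoff >= nyquist:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {nyquist} Hz")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    T = ts.n_timepoints
    freqs = np.fft.rfftfreq(T, d=ts.tr)
    spec = np.fft.rfft(ts.values, axis=0)
    spec[freqs > cutoff, :] = 0.0
    filtered = np.fft.irfft(spec, n=T, axis=0)
    return replace(ts, values=filtered)


def regress_global_signal(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Residualize every regional series on [intercept, global mean signal].

    The global signal is the across-region mean at each time point.  Output
    residuals are exactly orthogonal to (zero-correlated with) the global
    mean.  A constant global signal carries no direction to regress on; the
    series are then only mean-centered, with a warning.
    """
    if ts.n_timepoints <= 2:
        raise ValueError("need more than 2 time points for regression")
    g = ts.values.mean(axis=1)
    centered = ts.values - ts.values.mean(axis=0, keepdims=True)
    gc = g - g.mean()
    denom = float(gc @ gc)
    if denom == 0.0:
        warnings.warn("global signal is constant; returning mean-centered series")
        return replace(ts, values=centered)
    beta = (gc @ centered) / denom  # per-region slope
    residuals = centered - np.outer(gc, beta)
    return replace(ts, values=residuals)


def _gaussian_kernel2d(fwhm_mm: float, pixel_size_mm: Sequence[float], size: int) -> np.ndarray:
    if size % 2 != 1:
        raise ValueError("kernel size must be odd")
    sigmas = [fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / p for p in pixel_size_mm]
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=float)
    gx = np.exp(-0.5 * (ax / sigmas[0]) ** 2)
    gy = np.exp(-0.5 * (ax / sigmas[1]) ** 2)
    k = np.outer(gx, gy)
    return k / k.sum()


def smooth_image(
    volume_series: np.ndarray,
    pixel_size_mm: Optional[Sequence[float]] = None,
    kernel_size: int = 3,
    fwhm_mm: float = 0.6,
) -> np.ndarray:
    """In-plane (2-D) Gaussian smoothing of a 4-D series, slice by slice.

    ``volume_series`` is (X, Y, Z, T); each (X, Y) slice of each volume is
    convolved with a ``kernel_size`` x ``kernel_size`` truncated Gaussian of
    the stated FWHM.  The kernel is normalized to unit sum, so constant
    images are unchanged away from the border and the total image sum is
    preserved up to boundary truncation (zero padding).
    """
    data = np.asarray(volume_series, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4-D (X, Y, Z, T) array")
    if pixel_size_mm is None:
        raise ValueError("in-plane pixel sizes (mm) are required for smoothing")
    px = tuple(float(p) for p in pixel_size_mm)
    if len(px) != 2 or min(px) <= 0:
        raise ValueError("pixel_size_mm must be two positive in-plane sizes")
    kernel = _gaussian_kernel2d(fwhm_mm, px, kernel_size)
    out = np.empty_like(data)
    for z in range(data.shape[2]):
        for t in range(data.shape[3]):
            out[:, :, z, t] = ndimage.convolve(
                data[:, :, z, t], kernel, mode="constant", cval=0.0
            )
    return out


def extract_roi_timeseries(
    volume_series: np.ndarray,
    label_map: np.ndarray,
    atlas,
    tr: float = 1.0,
    label_values: Optional[Sequence[int]] = None,
) -> RoiTimeSeries:
    """Label-mean regional time courses from a 4-D series.

    ``label_map`` holds one integer label per voxel; by default label value
    ``i + 1`` maps onto ``atlas.regions[i]`` (0 = background).  Every region
    must own at least one voxel.
    """
    data = np.asarray(volume_series, dtype=float)
    lbl = np.asarray(label_map)
    if data.ndim != 4:
        raise ValueError("expected a 4-D (X, Y, Z, T) array")
    if lbl.shape != data.shape[:3]:
        raise ValueError("label map shape must match the spatial grid")
    regions = list(atlas.regions)
    if label_values is None:
        label_values = list(range(1, len(regions) + 1))
    if len(label_values) != len(regions):
        raise ValueError("need one label value per atlas region")
    flat_lbl = lbl.reshape(-1)
    n_lab = int(flat_lbl.max()) + 1
    counts = np.bincount(flat_lbl, minlength=n_lab)
    for region, lv in zip(regions, label_values):
        if lv >= n_lab or counts[lv] == 0:
            raise ValueError(f"region {region.abbreviation!r} (label {lv}) has no voxels")
    T = data.shape[3]
    flat = data.reshape(-1, T)
    sums = np.zeros((n_lab, T))
    np.add.at(sums, flat_lbl, flat)
    lv = np.asarray(label_values)
    means = sums[lv] / counts[lv, None]
    return RoiTimeSeries(
        values=means.T, tr=tr, labels=tuple(r.abbreviation for r in regions)
    )


def temporal_snr(volume_series: np.ndarray, mask: np.ndarray) -> TsnrResult:
    """Mean over mask voxels of temporal mean / temporal SD.

    Voxels with zero temporal SD are excluded from the average and counted
    in the result; a mask in which every voxel has zero SD is rejected.
    """
    data = np.asarray(volume_series, dtype=float)
    m = np.asarray(mask).astype(bool)
    if data.ndim != 4:
        raise ValueError("expected a 4-D (X, Y, Z, T) array")
    if m.shape != data.shape[:3]:
        raise ValueError("mask shape must match the spatial grid")
    if not m.any():
        raise ValueError("mask is empty")
    vox = data[m]  # (n_voxels, T)
    mean = vox.mean(axis=1)
    sd = vox.std(axis=1, ddof=1)
    valid = sd > 0
    n_zero = int((~valid).sum())
    if not valid.any():
        raise ValueError("all mask voxels have zero temporal SD")
    value = float((mean[valid] / sd[valid]).mean())
    return TsnrResult(value, n_voxels=int(valid.sum()), n_zero_sd=n_zero)
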