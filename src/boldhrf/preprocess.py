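"""Slice-timing correction, baseline-drift removal and percent conversion.

Drift removal follows the double-boxcar scheme: the baseline is the series
smoothed twice with a unit-area RECT kernel whose duration defaults to the
trial repetition period, then subtracted. Smoothing twice with a boxcar of
``L`` samples is algebraically identical to smoothing once with a triangular
kernel of ``2L - 1`` samples; the implementation pads the series by
reflection before filtering so that identity holds to machine precision and
constant series map to exactly zero.

With the kernel matched to the trial period, the moving average of the
periodic response train is (away from run edges) the constant per-trial mean,
so the evoked response survives detrending nearly intact; the residual
per-trial-mean offset is restored downstream by the endpoint baseline
adjustment of each epoch.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import InsufficientDataError, InvalidArgumentError, InvalidDataError
from .series import RunSeries

__all__ = [
    "slice_time_correct",
    "smooth_rect_twice",
    "remove_baseline_drift",
    "to_percent_change",
]


def slice_time_correct(
    data4d: np.ndarray,
    tr_seconds: float,
    slice_offsets,
    reference_offset: float = 0.0,
) -> np.ndarray:
    """Resample every slice's time courses to a common acquisition time.

    Slice ``z`` of volume ``k`` is acquired at ``k*tr + offset[z]``; each
    voxel's series is interpolated with a cubic spline — after replicating
    the first and last time frames by one TR on either side — and evaluated
    at ``k*tr + reference_offset``. Output shape equals input shape.
    """
    data4d = np.asarray(data4d, dtype=float)
    if data4d.ndim != 4:
        raise InvalidArgumentError("expected a 4-D array (x, y, slice, time)")
    nz, nt = data4d.shape[2], data4d.shape[3]
    offsets = np.asarray(slice_offsets, dtype=float)
    if offsets.shape != (nz,):
        raise InvalidArgumentError("one slice offset per slice required")
    if np.any(offsets < 0) or np.any(offsets >= tr_seconds):
        raise InvalidArgumentError("slice offsets must lie in [0, tr)")
    if not (0 <= reference_offset < tr_seconds):
        raise InvalidArgumentError("reference_offset must lie in [0, tr)")
    if nt < 4:
        raise InsufficientDataError("slice-timing correction needs >= 4 frames")

    out = np.empty_like(data4d)
    base_t = np.arange(nt) * tr_seconds
    eval_t = base_t + reference_offset
    for z in range(nz):
        if offsets[z] == reference_offset:
            out[:, :, z, :] = data4d[:, :, z, :]
            continue
        t = base_t + offsets[z]
        # replicate end frames so the spline does not extrapolate wildly
        t_pad = np.concatenate(([t[0] - tr_seconds], t, [t[-1] + tr_seconds]))
        y = data4d[:, :, z, :]
        y_pad = np.concatenate((y[:, :, :1], y, y[:, :, -1:]), axis=2)
        spline = CubicSpline(t_pad, y_pad, axis=2)
        out[:, :, z, :] = spline(np.clip(eval_t, t_pad[0], t_pad[-1]))
    return out


def _rect_samples(kernel_duration: float, tr_seconds: float) -> int:
    length = int(round(kernel_duration / tr_seconds))
    if length < 2:
        raise InvalidArgumentError("kernel must span at least 2 samples (>= 2 TR)")
    return length


def _reflect_pad(values: np.ndarray, pad: int) -> np.ndarray:
    """Whole-sample reflection padding of arbitrary width.

    Uses the ``2(n-1)``-periodic reflected extension, so ``pad`` may exceed
    the series length (unlike ``np.pad(mode='reflect')``).
    """
    n = values.size
    if n == 1:
        return np.full(n + 2 * pad, values[0])
    period = np.concatenate((values, values[n - 2 : 0 : -1]))
    idx = np.arange(-pad, n + pad) % period.size
    return period[idx]


def smooth_rect_twice(
    values: np.ndarray, length: int
) -> np.ndarray:
    """Smooth a 1-D series twice with a unit-area boxcar of ``length``
    samples, reflect-padded; exactly equal to one triangular smoothing of
    width ``2*length - 1``."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if length > n:
        raise InvalidArgumentError("kernel longer than series")
    pad = 2 * length
    padded = _reflect_pad(values, pad)
    box = np.full(length, 1.0 / length)
    full = np.convolve(np.convolve(padded, box), box)
    # the double-box kernel has 2*length - 1 taps centred at index length - 1
    start = pad + (length - 1)
    return full[start : start + n]


def remove_baseline_drift(
    series: RunSeries, kernel_duration_seconds: float
) -> tuple[RunSeries, np.ndarray]:
    """Estimate and subtract slow baseline drift.

    The baseline is the series smoothed twice with a unit-area RECT kernel
    of the given duration (default choice upstream: the trial period).
    Returns ``(detrended_series, baseline)``; a constant series detrends to
    exactly zero.
    """
    if kernel_duration_seconds <= 0:
        raise InvalidArgumentError("kernel_duration_seconds must be positive")
    length = _rect_samples(kernel_duration_seconds, series.tr_seconds)
    baseline = smooth_rect_twice(series.values, length)
    meta = dict(series.meta)
    meta["detrended"] = {"kernel_duration_seconds": kernel_duration_seconds}
    out = RunSeries(
        values=series.values - baseline,
        tr_seconds=series.tr_seconds,
        units=series.units,
        meta=meta,
    )
    return out, baseline


def to_percent_change(
    detrended: RunSeries, raw_run_mean: float | None = None
) -> RunSeries:
    """Convert a detrended raw-unit series to percent signal change.

    The denominator is the mean of the *raw* run (before detrending); pass
    it explicitly, or leave ``None`` to use ``meta['raw_run_mean']`` set by
    the pipeline.
    """
    if detrended.units != "raw":
        raise InvalidDataError("series already in percent units")
    if raw_run_mean is None:
        raw_run_mean = detrended.meta.get("raw_run_mean")
    if raw_run_mean is None:
        raise InvalidDataError("raw run mean required for percent conversion")
    if raw_run_mean <= 0:
        raise InvalidDataError("raw run mean must be positive")
    meta = dict(detrended.meta)
    meta["raw_run_mean"] = float(raw_run_mean)
    return RunSeries(
        values=100.0 * detrended.values / raw_run_mean,
        tr_seconds=detrended.tr_seconds,
        units="percent",
        meta=meta,
    )


def preprocess_run(
    run: RunSeries, kernel_duration_seconds: float
) -> RunSeries:
    """Drift-remove a raw run and convert to percent signal change."""
    if run.units != "raw":
        raise InvalidDataError("preprocess_run expects a raw-unit series")
    mean = float(run.values.mean())
    detrended, _ = remove_baseline_drift(run, kernel_duration_seconds)
    detrended.meta["raw_run_mean"] = mean
    return to_percent_change(detrended, mean)
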