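"""Model-free HRF descriptors on upsampled trial curves.

Curves are upsampled by a factor of 5 with cubic Hermite-spline
interpolation (finite-difference / Catmull-Rom tangents, not the
monotonicity-preserving variant). Five descriptors are then read off the
fine-grid curve:

* ``p_amp``   — global maximum (percent signal change);
* ``ttp``     — time of that maximum from trial onset (earliest tie wins);
* ``onset``   — first time the curve reaches half of ``p_amp``;
* ``fwhm``    — falling half-max crossing minus onset;
* ``undershoot_amp`` — minimum of the curve after the falling half-max
  crossing, clamped to 0 when nothing goes below baseline (signed, <= 0).

Half-max crossing times are refined by linear interpolation between fine
samples. A curve with no positive excursion has no defined parameters and
raises :class:`~boldhrf.errors.NoPositivePeakError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicHermiteSpline

from .errors import InvalidArgumentError, NoPositivePeakError

__all__ = [
    "HrfParams",
    "upsample",
    "estimate_params",
    "estimate_params_batch",
    "screen_voxels",
    "UPSAMPLE_FACTOR",
]

UPSAMPLE_FACTOR = 5
# maxima in the final quarter of the epoch are suspect (drift residue)
_LATE_PEAK_FRACTION = 0.75


@dataclass
class HrfParams:
    """The five scalar HRF descriptors (plus CNR, filled by the bootstrap)."""

    p_amp: float
    ttp_seconds: float
    onset_seconds: float
    fwhm_seconds: float
    undershoot_amp: float
    cnr: float = float("nan")
    fall_time_seconds: float = float("nan")
    undershoot_time_seconds: float = float("nan")
    flags: dict = field(default_factory=dict)


def _tangents(y: np.ndarray, dt: float) -> np.ndarray:
    """Catmull-Rom (central finite-difference) tangents, one-sided at ends."""
    m = np.empty_like(y)
    m[..., 1:-1] = (y[..., 2:] - y[..., :-2]) / (2.0 * dt)
    m[..., 0] = (y[..., 1] - y[..., 0]) / dt
    m[..., -1] = (y[..., -1] - y[..., -2]) / dt
    return m


def upsample(
    curve: np.ndarray, tr_seconds: float, factor: int = UPSAMPLE_FACTOR
) -> tuple[np.ndarray, np.ndarray]:
    """Upsample curve(s) onto a grid of step ``tr/factor``.

    Accepts a 1-D curve or a batch with time on the last axis. Original
    samples are reproduced exactly at their grid points. Returns
    ``(fine_times, fine_curves)``.
    """
    curve = np.asarray(curve, dtype=float)
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise InvalidArgumentError("factor must be a positive integer")
    n = curve.shape[-1]
    if n < 4:
        raise InvalidArgumentError("upsampling needs >= 4 samples")
    coarse_t = np.arange(n) * tr_seconds
    if factor == 1:
        return coarse_t, curve.copy()
    fine_t = np.arange((n - 1) * factor + 1) * (tr_seconds / factor)
    spline = CubicHermiteSpline(coarse_t, curve, _tangents(curve, tr_seconds), axis=-1)
    fine = spline(fine_t)
    # pin the knots exactly (spline evaluation is exact up to rounding)
    fine[..., ::factor] = curve
    return fine_t, fine


def estimate_params_batch(
    curves: np.ndarray, tr_seconds: float, factor: int = UPSAMPLE_FACTOR
) -> dict[str, np.ndarray]:
    """Vectorized descriptor estimation for a stack of curves.

    Returns arrays keyed ``p_amp, ttp, onset, fwhm, undershoot, fall_time,
    undershoot_time, valid, late_peak, no_fall``. Rows without a positive
    excursion get NaN descriptors and ``valid=False`` (callers decide
    whether that is an error).
    """
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    t, fine = upsample(curves, tr_seconds, factor)
    dt = t[1] - t[0] if t.size > 1 else tr_seconds
    n, nf = fine.shape
    rows = np.arange(n)

    p_idx = np.argmax(fine, axis=1)  # earliest maximum
    p_amp = fine[rows, p_idx]
    # a positive excursion must exist in the measured samples themselves,
    # not only as interpolation overshoot
    valid = (p_amp > 0) & (curves.max(axis=1) > 0)
    half = 0.5 * p_amp
    col = np.arange(nf)[None, :]

    # onset: first fine sample at/above half-max, refined by linear interp
    ge = fine >= half[:, None]
    onset_idx = np.argmax(ge, axis=1)
    j = onset_idx
    has_prev = j > 0
    jp = np.where(has_prev, j - 1, 0)
    y0, y1 = fine[rows, jp], fine[rows, j]
    denom = y1 - y0
    frac = np.where((denom > 0) & has_prev, (half - y0) / np.where(denom == 0, 1, denom), 0.0)
    onset = t[jp] + frac * dt
    onset = np.where(has_prev, onset, t[onset_idx])

    # falling half-max crossing: first sample after the peak below half
    after = col > p_idx[:, None]
    below = fine < half[:, None]
    fall_mask = after & below
    any_fall = fall_mask.any(axis=1)
    f_idx = np.argmax(fall_mask, axis=1)
    f_idx = np.where(any_fall, f_idx, nf - 1)
    fp = np.maximum(f_idx - 1, 0)
    z0, z1 = fine[rows, fp], fine[rows, f_idx]
    dz = z0 - z1
    ffrac = np.where((dz > 0) & any_fall, (z0 - half) / np.where(dz == 0, 1, dz), 1.0)
    fall_time = np.where(any_fall, t[fp] + ffrac * dt, t[-1])

    fwhm = fall_time - onset

    # undershoot: minimum after the falling crossing, clamped at 0
    tail = col >= f_idx[:, None]
    masked = np.where(tail, fine, np.inf)
    u_idx = np.argmin(masked, axis=1)
    u_min = masked[rows, u_idx]
    u_min = np.where(np.isfinite(u_min), u_min, 0.0)
    undershoot = np.where(u_min < 0, u_min, 0.0)
    undershoot_time = t[u_idx].astype(float)

    ttp = t[p_idx].astype(float)
    late_peak = ttp > _LATE_PEAK_FRACTION * t[-1]
    nanify = ~valid
    for arr in (p_amp, ttp, onset, fwhm, undershoot, fall_time, undershoot_time):
        arr[nanify] = np.nan
    return {
        "p_amp": p_amp,
        "ttp": ttp,
        "onset": onset,
        "fwhm": fwhm,
        "undershoot": undershoot,
        "fall_time": fall_time,
        "undershoot_time": undershoot_time,
        "valid": valid,
        "late_peak": late_peak & valid,
        "no_fall": (~any_fall) & valid,
    }


def estimate_params(
    curve: np.ndarray, tr_seconds: float, factor: int = UPSAMPLE_FACTOR
) -> HrfParams:
    """Estimate the HRF descriptors of one baseline-adjusted curve."""
    res = estimate_params_batch(np.asarray(curve, dtype=float)[None, :], tr_seconds, factor)
    if not res["valid"][0]:
        raise NoPositivePeakError("curve has no positive excursion")
    return HrfParams(
        p_amp=float(res["p_amp"][0]),
        ttp_seconds=float(res["ttp"][0]),
        onset_seconds=float(res["onset"][0]),
        fwhm_seconds=float(res["fwhm"][0]),
        undershoot_amp=float(res["undershoot"][0]),
        fall_time_seconds=float(res["fall_time"][0]),
        undershoot_time_seconds=float(res["undershoot_time"][0]),
        flags={
            "late_peak": bool(res["late_peak"][0]),
            "no_fall": bool(res["no_fall"][0]),
        },
    )


def screen_voxels(p_amp: np.ndarray, cnr: np.ndarray) -> np.ndarray:
    """Activation screen: keep voxels with CNR > 3 and peak amplitude > 0.2%.

    Negative-response voxels never pass (their ``p_amp`` is non-positive or
    NaN and NaN comparisons are False).
    """
    p_amp = np.asarray(p_amp, dtype=float)
    cnr = np.asarray(cnr, dtype=float)
    with np.errstate(invalid="ignore"):
        return (cnr > 3.0) & (p_amp > 0.2)
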