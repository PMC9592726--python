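"""Two-level bootstrap inference for HRF curves and parameters.

Within a subject, the single-trial epochs of an ROI are resampled with
replacement and averaged; 500 such replicates give per-timepoint 68%
percentile confidence intervals (16th/84th), a scalar variability (the mean
half-width of that interval, which equals the standard error of the mean
for Gaussian noise) and CNR = peak amplitude / variability. Descriptors are
estimated on each replicate's mean curve, not on single epochs, because
single-epoch CNR is far too low for stable half-max crossings.

Across subjects, each of 2,000 group replicates draws one within-subject
replicate (curve + carried parameters) per subject and averages across
subjects; subjects themselves are not resampled. Group 68% CIs, parameter
histograms and comparison p-values come from those replicates. Because the
resampling distribution is built once over the entire sample set, no
additional multiple-comparison correction is applied.

Undershoot significance
-----------------------
The descriptive ``undershoot_amp`` is an extremum (the post-fall minimum)
and is therefore biased below zero under resampling noise; a test built on
it would reject even when no undershoot exists. Significance is instead
assessed on the *late-window amplitude*: the mean of each group replicate
curve over the final quarter of the epoch. That window is fixed by the
trial design — the trial period is chosen so the response has evolved and
decayed before the next trial — so under a null HRF that returns to
baseline the statistic is centred at zero and the test is calibrated, while
a genuine undershoot (which persists well past the positive lobe) pulls it
negative. ``p`` is the fraction of group replicates whose late-window
amplitude is at or above baseline (zero); ``p < 0.05`` declares a
significant undershoot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .epoching import EpochSet
from .errors import (
    GridMismatchError,
    InsufficientDataError,
    InvalidArgumentError,
)
from .hrf_params import HrfParams, estimate_params, estimate_params_batch, upsample

__all__ = [
    "BootstrapResult",
    "GroupResult",
    "bootstrap_within",
    "bootstrap_across",
    "undershoot_pvalue",
    "compare_params",
    "resample_curves",
]

PARAM_COLUMNS = ("p_amp", "ttp", "onset", "fwhm", "undershoot")
DEFAULT_COMMON_DT = 0.25  # seconds; divides both 1.25-s and 1.5-s TRs
# the undershoot test averages each replicate curve over the final quarter
# of the epoch: the trial period is designed to let the response decay, so
# this window is baseline under the null and negative under an undershoot
LATE_WINDOW_FRACTION = 0.75


@dataclass
class BootstrapResult:
    """Within-subject bootstrap summary for one ROI."""

    mean_curve: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    variability: float
    cnr: float
    params: HrfParams | None
    param_samples: pd.DataFrame
    replicate_curves: np.ndarray
    tr_seconds: float
    n_boot: int
    seed: int
    roi_label: str = "roi"
    subject_id: str = "sub-01"
    flags: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.mean_curve.size) * self.tr_seconds

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_seconds": self.times,
                "mean": self.mean_curve,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )

    def to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tag = f"{self.subject_id}_{self.roi_label}"
        self.curve_frame().to_csv(
            outdir / f"{tag}_curve.tsv", sep="\t", index=False, float_format="%.10g"
        )
        self.param_samples.to_csv(
            outdir / f"{tag}_param_samples.tsv",
            sep="\t",
            index=False,
            float_format="%.10g",
        )
        report = {
            "subject_id": self.subject_id,
            "roi_label": self.roi_label,
            "variability": self.variability,
            "cnr": self.cnr,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "flags": self.flags,
            "params": None
            if self.params is None
            else {
                "p_amp": self.params.p_amp,
                "ttp_seconds": self.params.ttp_seconds,
                "onset_seconds": self.params.onset_seconds,
                "fwhm_seconds": self.params.fwhm_seconds,
                "undershoot_amp": self.params.undershoot_amp,
                "cnr": self.cnr,
            },
        }
        (outdir / f"{tag}_report.json").write_text(json.dumps(report, indent=2))


@dataclass
class GroupResult:
    """Across-subject bootstrap summary for one ROI/field condition."""

    times: np.ndarray
    group_mean_curve: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    param_samples: pd.DataFrame
    undershoot_stat_samples: np.ndarray
    p_undershoot: float
    n_boot2: int
    seed: int
    subject_ids: tuple[str, ...] = ()
    roi_label: str = "roi"
    flags: dict = field(default_factory=dict)

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_seconds": self.times,
                "mean": self.group_mean_curve,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def bootstrap_within(
    epochs: EpochSet,
    n_boot: int = 500,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> BootstrapResult:
    """Within-subject bootstrap of the mean HRF of one ROI.

    Each replicate resamples the epochs with replacement and averages;
    descriptors are estimated on every replicate mean (vectorized). CIs are
    16th/84th percentiles per timepoint; variability is the mean CI
    half-width; CNR is the mean curve's peak over that variability. When all
    epochs are identical the variability is zero and CNR is reported as
    ``inf`` with a ``degenerate`` flag.
    """
    if epochs.n_epochs < 2:
        raise InsufficientDataError("bootstrap needs >= 2 epochs")
    if n_boot < 2:
        raise InvalidArgumentError("n_boot must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    e = epochs.epochs
    n = epochs.n_epochs
    idx = rng.integers(0, n, size=(n_boot, n))
    reps = e[idx].mean(axis=1)
    mean_curve = reps.mean(axis=0)
    ci_low, ci_high = np.percentile(reps, [16.0, 84.0], axis=0)
    variability = float(np.mean(0.5 * (ci_high - ci_low)))

    batch = estimate_params_batch(reps, epochs.tr_seconds)
    param_samples = pd.DataFrame({k: batch[k] for k in PARAM_COLUMNS})
    param_samples["valid"] = batch["valid"]

    flags: dict = {}
    try:
        params = estimate_params(mean_curve, epochs.tr_seconds)
        flags.update(params.flags)
    except Exception:
        params = None
        flags["no_positive_peak"] = True

    if params is None:
        cnr = float("nan")
    elif variability == 0.0:
        cnr = float("inf")
        flags["degenerate"] = True
    else:
        cnr = params.p_amp / variability
    if params is not None:
        params.cnr = cnr

    return BootstrapResult(
        mean_curve=mean_curve,
        ci_low=ci_low,
        ci_high=ci_high,
        variability=variability,
        cnr=cnr,
        params=params,
        param_samples=param_samples,
        replicate_curves=reps,
        tr_seconds=epochs.tr_seconds,
        n_boot=n_boot,
        seed=seed,
        roi_label=epochs.roi_label,
        subject_id=epochs.subject_id,
        flags=flags,
    )


def resample_curves(
    curves: np.ndarray, tr_seconds: float, new_times: np.ndarray
) -> np.ndarray:
    """Resample curve(s) onto an arbitrary time grid with the same cubic
    Hermite interpolation used for parameter estimation."""
    from scipy.interpolate import CubicHermiteSpline

    from .hrf_params import _tangents

    curves = np.asarray(curves, dtype=float)
    n = curves.shape[-1]
    if n < 4:
        raise InvalidArgumentError("resampling needs >= 4 samples")
    spline = CubicHermiteSpline(
        np.arange(n) * tr_seconds, curves, _tangents(curves, tr_seconds), axis=-1
    )
    return spline(new_times)


def _common_grid(results: Sequence[BootstrapResult], dt: float) -> np.ndarray:
    tmax = min((r.mean_curve.size - 1) * r.tr_seconds for r in results)
    n = int(np.floor(tmax / dt + 1e-9)) + 1
    return np.arange(n) * dt


def bootstrap_across(
    subject_results: Sequence[BootstrapResult],
    n_boot2: int = 2000,
    seed: int = 0,
    resample_to_common_grid: bool = False,
    common_dt: float = DEFAULT_COMMON_DT,
    reestimate_params: bool = False,
) -> GroupResult:
    """Across-subject bootstrap of the group mean HRF and its parameters.

    Each of ``n_boot2`` group replicates draws one within-subject replicate
    per subject (uniformly with replacement over each subject's replicates)
    and averages curves and carried parameters across subjects. Subjects
    with different TRs require ``resample_to_common_grid=True``, which
    regrids every curve onto a ``common_dt`` grid (0.25 s divides both
    supported TRs) before averaging; parameter averaging needs no regridding.
    """
    results = list(subject_results)
    if len(results) < 2:
        raise InsufficientDataError("group bootstrap needs >= 2 subjects")
    trs = {round(r.tr_seconds, 9) for r in results}
    lengths = {r.mean_curve.size for r in results}
    if (len(trs) > 1 or len(lengths) > 1) and not resample_to_common_grid:
        raise GridMismatchError(
            "subjects are on different time grids; pass resample_to_common_grid=True"
        )
    rng = np.random.default_rng(seed)

    if len(trs) > 1 or len(lengths) > 1 or resample_to_common_grid:
        times = _common_grid(results, common_dt)
        rep_curves = [
            resample_curves(r.replicate_curves, r.tr_seconds, times) for r in results
        ]
        mean_curves = [
            resample_curves(r.mean_curve, r.tr_seconds, times) for r in results
        ]
        out_tr = common_dt
    else:
        times = results[0].times
        rep_curves = [r.replicate_curves for r in results]
        mean_curves = [r.mean_curve for r in results]
        out_tr = results[0].tr_seconds

    S = len(results)
    group_reps = np.zeros((n_boot2, times.size))
    param_acc = {k: np.zeros(n_boot2) for k in PARAM_COLUMNS}
    for s, r in enumerate(results):
        draws = rng.integers(0, r.replicate_curves.shape[0], size=n_boot2)
        group_reps += rep_curves[s][draws]
        samples = r.param_samples
        for k in PARAM_COLUMNS:
            param_acc[k] += samples[k].to_numpy()[draws]
    group_reps /= S
    if reestimate_params:
        batch = estimate_params_batch(group_reps, out_tr)
        param_samples = pd.DataFrame({k: batch[k] for k in PARAM_COLUMNS})
    else:
        param_samples = pd.DataFrame({k: v / S for k, v in param_acc.items()})

    group_mean_curve = np.mean(mean_curves, axis=0)
    ci_low, ci_high = np.percentile(group_reps, [16.0, 84.0], axis=0)

    # late-window amplitude: mean of each replicate curve over the fixed
    # final quarter of the epoch (design-determined, not data-selected)
    flags: dict = {}
    fine_t, fine_reps = upsample(group_reps, out_tr)
    window = fine_t >= LATE_WINDOW_FRACTION * fine_t[-1]
    undershoot_stat = fine_reps[:, window].mean(axis=1)
    frac_ge = float(np.mean(undershoot_stat >= 0.0))
    p_under = max(frac_ge, 1.0 / n_boot2)
    if frac_ge == 0.0:
        flags["p_undershoot_floored"] = True

    return GroupResult(
        times=times,
        group_mean_curve=group_mean_curve,
        ci_low=ci_low,
        ci_high=ci_high,
        param_samples=param_samples,
        undershoot_stat_samples=undershoot_stat,
        p_undershoot=p_under,
        n_boot2=n_boot2,
        seed=seed,
        subject_ids=tuple(r.subject_id for r in results),
        roi_label=results[0].roi_label,
        flags=flags,
    )


def undershoot_pvalue(group: GroupResult) -> float:
    """Fraction of group replicates whose late-window amplitude is at or
    above baseline, floored at ``1/n_boot2``; ``p < 0.05`` means a
    significant undershoot."""
    frac = float(np.mean(group.undershoot_stat_samples >= 0.0))
    return max(frac, 1.0 / group.n_boot2)


def compare_params(
    group_a: GroupResult, group_b: GroupResult, param_name: str
) -> float:
    """Two-sided bootstrap p-value for a parameter difference between groups.

    Pairs the two groups' replicate parameter means by index and reports
    ``2 * min(frac(diff >= 0), frac(diff <= 0))`` (ties count toward both
    sides, so identical distributions give p = 1), floored at ``1/n`` and
    capped at 1.
    """
    for g in (group_a, group_b):
        if param_name not in g.param_samples.columns:
            raise InvalidArgumentError(f"no parameter samples for {param_name!r}")
    a = group_a.param_samples[param_name].to_numpy()
    b = group_b.param_samples[param_name].to_numpy()
    n = min(a.size, b.size)
    diff = a[:n] - b[:n]
    ok = np.isfinite(diff)
    if not ok.any():
        return float("nan")
    diff = diff[ok]
    p = 2.0 * min(float(np.mean(diff >= 0)), float(np.mean(diff <= 0)))
    return float(min(max(p, 1.0 / diff.size), 1.0))
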