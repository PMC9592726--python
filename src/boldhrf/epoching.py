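"""Cut runs into single-trial HRF epochs and form ROI mean responses.

The ROI time series is averaged across voxels *before* epoching; runs are
epoched independently (never across a run boundary) and the trials pooled,
so drift discontinuities between runs cannot leak into an epoch. Each epoch
is baseline-adjusted by subtracting the mean of its first and last samples,
so the HRF starts from near-zero amplitude.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd

from .acquisition import AcquisitionSpec
from .errors import EmptyRoiError, InsufficientDataError, InvalidArgumentError
from .series import RunSeries

__all__ = [
    "EpochSet",
    "average_roi",
    "extract_epochs",
    "baseline_adjust",
    "mean_hrf",
    "epochs_from_arrays",
]


@dataclass
class EpochSet:
    """Single-trial HRF curves for one ROI of one subject.

    ``epochs`` has shape ``(n_epochs, n_timepoints)`` in percent units, with
    timepoint ``k`` at ``k * tr_seconds`` after trial onset. This is the
    unit of bootstrap resampling.
    """

    epochs: np.ndarray
    tr_seconds: float
    roi_label: str = "roi"
    subject_id: str = "sub-01"
    field_strength_tesla: float = float("nan")
    baseline_adjusted: bool = False
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.epochs = np.atleast_2d(np.asarray(self.epochs, dtype=float))
        if self.tr_seconds <= 0:
            raise InvalidArgumentError("tr_seconds must be positive")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.epochs.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.tr_seconds

    def to_tsv(self, path: str | Path) -> None:
        """One row per epoch; JSON metadata sidecar."""
        path = Path(path)
        cols = [f"t{k}" for k in range(self.n_timepoints)]
        pd.DataFrame(self.epochs, columns=cols).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )
        sidecar = {
            "tr_seconds": self.tr_seconds,
            "roi_label": self.roi_label,
            "subject_id": self.subject_id,
            "field_strength_tesla": self.field_strength_tesla,
            "baseline_adjusted": self.baseline_adjusted,
            "n_epochs": self.n_epochs,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EpochSet":
        path = Path(path)
        epochs = pd.read_csv(path, sep="\t").to_numpy(dtype=float)
        side = json.loads(path.with_suffix(".json").read_text())
        return cls(
            epochs=epochs,
            tr_seconds=side["tr_seconds"],
            roi_label=side.get("roi_label", "roi"),
            subject_id=side.get("subject_id", "sub-01"),
            field_strength_tesla=side.get("field_strength_tesla", float("nan")),
            baseline_adjusted=side.get("baseline_adjusted", False),
        )


def average_roi(
    data4d: np.ndarray,
    mask: np.ndarray,
    roi_label: int,
    tr_seconds: float,
    units: str = "raw",
) -> RunSeries:
    """Unweighted mean time series across the voxels of one ROI label."""
    data4d = np.asarray(data4d, dtype=float)
    sel = np.asarray(mask) == roi_label
    if not sel.any():
        raise EmptyRoiError(f"label {roi_label} selects no voxels")
    return RunSeries(
        values=data4d[sel].mean(axis=0),
        tr_seconds=tr_seconds,
        units=units,
        meta={"roi_label": int(roi_label), "n_voxels": int(sel.sum())},
    )


def extract_epochs(
    runs: RunSeries | Iterable[RunSeries],
    acq: AcquisitionSpec,
    roi_label: str = "roi",
    subject_id: str = "sub-01",
    field_strength_tesla: float = float("nan"),
) -> EpochSet:
    """Cut each run into trial-period epochs, discarding the lead-in.

    Epochs start at ``leadin + k * trial_period``; runs are cut separately
    and pooled, giving exactly ``n_runs * n_trials_per_run`` epochs of
    ``trial_period / tr`` samples.
    """
    if isinstance(runs, RunSeries):
        runs = [runs]
    runs = list(runs)
    spt = acq.samples_per_trial
    need = acq.leadin_volumes + acq.n_trials_per_run * spt
    blocks = []
    for run in runs:
        if abs(run.tr_seconds - acq.tr_seconds) > 1e-9:
            raise InvalidArgumentError("run TR does not match acquisition spec")
        if len(run) < need:
            raise InsufficientDataError(
                f"run has {len(run)} volumes, need {need} "
                f"(lead-in {acq.leadin_volumes} + {acq.n_trials_per_run} trials "
                f"x {spt} samples)"
            )
        body = run.values[acq.leadin_volumes : need]
        blocks.append(body.reshape(acq.n_trials_per_run, spt))
    return EpochSet(
        epochs=np.vstack(blocks),
        tr_seconds=acq.tr_seconds,
        roi_label=roi_label,
        subject_id=subject_id,
        field_strength_tesla=field_strength_tesla,
        meta={"n_runs": len(runs), "units": runs[0].units},
    )


def baseline_adjust(epochs: EpochSet) -> EpochSet:
    """Subtract the mean of each epoch's first and last samples (idempotent)."""
    if epochs.n_timepoints < 2:
        raise InsufficientDataError("baseline adjustment needs >= 2 timepoints")
    e = epochs.epochs
    offset = 0.5 * (e[:, 0] + e[:, -1])
    return replace(epochs, epochs=e - offset[:, None], baseline_adjusted=True)


def mean_hrf(epochs: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and sample SD (ddof=1) across epochs."""
    if epochs.n_epochs < 1:
        raise InsufficientDataError("mean_hrf needs at least one epoch")
    mean = epochs.epochs.mean(axis=0)
    if epochs.n_epochs > 1:
        sd = epochs.epochs.std(axis=0, ddof=1)
    else:
        sd = np.zeros_like(mean)
    return mean, sd


def epochs_from_arrays(
    epochs: np.ndarray,
    tr_seconds: float,
    **kwargs,
) -> EpochSet:
    """Convenience constructor for tests and simulation studies."""
    return EpochSet(epochs=epochs, tr_seconds=tr_seconds, **kwargs)
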