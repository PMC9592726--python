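"""Acquisition geometry and trial structure of an event-related fMRI session.

An :class:`AcquisitionSpec` captures everything the pipeline needs to know
about how a run was sampled: the volume repetition time (TR), the per-slice
acquisition offsets within a TR, and the trial train (trial period, trials
per run, number of runs, lead-in blank, stimulus duration).

Two presets mirror the acquisition geometries the package is designed
around: an ultra-high-field protocol (TR 1.25 s, 16 slices, 26.25-s trials,
17 trials/run, 5 runs) and a 3T protocol (TR 1.5 s, 10 slices, 25.5-s
trials, 17 trials/run, 8 runs), both with a 12-s lead-in and a 2-s stimulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["AcquisitionSpec", "preset_9p4t", "preset_3t", "PRESETS"]

_REL_TOL = 1e-9


def _ascending_offsets(n_slices: int, tr: float) -> tuple[float, ...]:
    """Sequential ascending acquisition: slice k read at k*TR/n_slices."""
    return tuple(k * tr / n_slices for k in range(n_slices))


@dataclass(frozen=True)
class AcquisitionSpec:
    """Sampling geometry and trial structure of one event-related session.

    Parameters
    ----------
    tr_seconds : float
        Volume repetition time in seconds.
    n_slices : int
        Number of slices per volume.
    trial_period_seconds : float
        Trial repetition period; must be an integer multiple of the TR so
        that each trial covers an exact number of volumes.
    n_trials_per_run : int
        Trials in each run.
    n_runs : int
        Runs per session.
    leadin_seconds : float
        Blank period at the start of each run, discarded before epoching.
    stim_duration_seconds : float
        Duration of the stimulus at each trial onset.
    slice_offsets : tuple of float, optional
        Acquisition time of each slice relative to the volume timestamp, in
        ``[0, tr)``. Defaults to sequential ascending order.
    """

    tr_seconds: float
    n_slices: int
    trial_period_seconds: float
    n_trials_per_run: int
    n_runs: int
    leadin_seconds: float = 0.0
    stim_duration_seconds: float = 2.0
    slice_offsets: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise InvalidArgumentError("tr_seconds must be positive")
        if self.n_slices < 1 or self.n_trials_per_run < 1 or self.n_runs < 1:
            raise InvalidArgumentError(
                "n_slices, n_trials_per_run and n_runs must be >= 1"
            )
        if self.trial_period_seconds <= 0:
            raise InvalidArgumentError("trial_period_seconds must be positive")
        if self.leadin_seconds < 0:
            raise InvalidArgumentError("leadin_seconds must be non-negative")
        if self.stim_duration_seconds <= 0:
            raise InvalidArgumentError("stim_duration_seconds must be positive")
        ratio = self.trial_period_seconds / self.tr_seconds
        if abs(ratio - round(ratio)) > _REL_TOL * ratio:
            raise InvalidArgumentError(
                "trial_period_seconds must be an integer multiple of tr_seconds "
                f"(got {self.trial_period_seconds} / {self.tr_seconds})"
            )
        if self.slice_offsets is None:
            object.__setattr__(
                self,
                "slice_offsets",
                _ascending_offsets(self.n_slices, self.tr_seconds),
            )
        else:
            offsets = tuple(float(o) for o in self.slice_offsets)
            if len(offsets) != self.n_slices:
                raise InvalidArgumentError(
                    "slice_offsets must have one entry per slice"
                )
            if any(o < 0 or o >= self.tr_seconds for o in offsets):
                raise InvalidArgumentError(
                    "slice offsets must lie in [0, tr_seconds)"
                )
            object.__setattr__(self, "slice_offsets", offsets)

    # -- derived sample counts ------------------------------------------------

    @property
    def samples_per_trial(self) -> int:
        """Exact number of volumes per trial period."""
        return round(self.trial_period_seconds / self.tr_seconds)

    @property
    def leadin_volumes(self) -> int:
        """Volumes covering the lead-in blank.

        The first trial starts on the first volume boundary at or after
        ``leadin_seconds``, so the lead-in is rounded up to whole volumes.
        """
        return math.ceil(self.leadin_seconds / self.tr_seconds - _REL_TOL)

    @property
    def volumes_per_run(self) -> int:
        return self.leadin_volumes + self.n_trials_per_run * self.samples_per_trial

    @property
    def run_duration_seconds(self) -> float:
        return self.volumes_per_run * self.tr_seconds

    @property
    def epochs_per_session(self) -> int:
        return self.n_trials_per_run * self.n_runs

    def trial_onsets_seconds(self) -> np.ndarray:
        """Trial-onset times within one run, relative to the run start."""
        start = self.leadin_volumes * self.tr_seconds
        return start + np.arange(self.n_trials_per_run) * self.trial_period_seconds

    def volume_times(self) -> np.ndarray:
        """Nominal timestamp of each volume in one run."""
        return np.arange(self.volumes_per_run) * self.tr_seconds

    def with_(self, **kwargs) -> "AcquisitionSpec":
        """Return a copy with the given fields replaced.

        Changing ``n_slices`` without giving ``slice_offsets`` regenerates
        default ascending offsets instead of keeping the stale tuple.
        """
        if "n_slices" in kwargs and "slice_offsets" not in kwargs:
            kwargs["slice_offsets"] = None
        return replace(self, **kwargs)


def preset_9p4t(n_runs: int = 5) -> AcquisitionSpec:
    """Ultra-high-field protocol: TR 1.25 s, 16 slices, 26.25-s trials,
    17 trials/run, 12-s lead-in, 2-s stimulus."""
    return AcquisitionSpec(
        tr_seconds=1.25,
        n_slices=16,
        trial_period_seconds=26.25,
        n_trials_per_run=17,
        n_runs=n_runs,
        leadin_seconds=12.0,
        stim_duration_seconds=2.0,
    )


def preset_3t(n_runs: int = 8) -> AcquisitionSpec:
    """3T protocol: TR 1.5 s, 10 slices, 25.5-s trials, 17 trials/run,
    12-s lead-in, 2-s stimulus."""
    return AcquisitionSpec(
        tr_seconds=1.5,
        n_slices=10,
        trial_period_seconds=25.5,
        n_trials_per_run=17,
        n_runs=n_runs,
        leadin_seconds=12.0,
        stim_duration_seconds=2.0,
    )


PRESETS = {"9.4T": preset_9p4t, "3T": preset_3t}
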