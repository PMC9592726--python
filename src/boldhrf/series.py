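"""Lightweight container for a single-ROI fMRI run time series."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["RunSeries"]


@dataclass
class RunSeries:
    """One run's time series for a single ROI (or voxel).

    Attributes
    ----------
    values : ndarray
        Time-ordered samples, one per volume.
    tr_seconds : float
        Sampling interval.
    units : str
        ``"raw"`` (scanner units) or ``"percent"`` (percent signal change).
        The only permitted transition is raw -> percent, performed once by
        :func:`boldhrf.preprocess.to_percent_change`.
    meta : dict
        Free-form provenance (simulation ground truth, processing history).
    """

    values: np.ndarray
    tr_seconds: float
    units: str = "raw"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InvalidArgumentError("RunSeries values must be 1-D")
        if self.tr_seconds <= 0:
            raise InvalidArgumentError("tr_seconds must be positive")
        if self.units not in ("raw", "percent"):
            raise InvalidArgumentError("units must be 'raw' or 'percent'")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.tr_seconds
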