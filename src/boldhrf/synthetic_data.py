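"""Synthetic event-related BOLD data with known ground truth.

Every downstream stage of the pipeline (drift removal, slice-timing
correction, epoching, HRF parameterization, bootstrap inference) is tested
against runs produced here, because the generative hemodynamic response and
the noise process are known exactly.

Generative HRF model
--------------------
The single-trial response is built from three independently tunable pieces:

* a gamma-variate positive lobe, reparameterized so that
  ``peak_time_seconds`` is the literal argmax and ``dispersion_seconds``
  acts like a Gaussian sigma near the peak (FWHM ~ 2.355 * dispersion);
* a delayed, wider gamma-variate undershoot lobe whose depth is
  ``undershoot_ratio`` times the peak;
* an additive exponentially damped oscillation ("ringing") starting at the
  peak, for the post-peak signal fluctuation some subjects show.

A trial response is the kernel averaged over the stimulus boxcar
(``stim_duration_seconds``) and rescaled so that ``amplitude_percent``
remains the literal peak of the trial response in percent signal change.
Runs superpose one trial response per trial onset, multiply onto a baseline
intensity, and add slow cosine drift, AR(1)-correlated Gaussian noise and
(optionally) Rician magnitude noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .acquisition import AcquisitionSpec
from .errors import ConfigurationError, InvalidArgumentError
from .series import RunSeries

__all__ = [
    "HrfModel",
    "NoiseModel",
    "cortical_model",
    "subcortical_model",
    "make_hrf_kernel",
    "trial_response",
    "evaluate_train",
    "simulate_roi_run",
    "simulate_session",
    "simulate_volume_run",
    "simulate_epochs",
    "write_session_tsv",
    "write_volume_nifti",
]

_FINE_DT = 0.01  # grid for continuous-model evaluation, seconds


@dataclass(frozen=True)
class HrfModel:
    """Ground-truth generative HRF parameters.

    ``amplitude_percent`` is the peak height of the trial response in
    percent signal change; ``undershoot_ratio`` (in [0, 1)) is the
    undershoot depth relative to that peak; the ringing term is an
    exponentially damped oscillation added after the peak.
    """

    amplitude_percent: float = 1.0
    peak_time_seconds: float = 6.0
    dispersion_seconds: float = 2.0
    undershoot_ratio: float = 0.0
    undershoot_delay_seconds: float = 9.0
    undershoot_dispersion_seconds: float | None = None
    ring_amplitude_percent: float = 0.0
    ring_frequency_hz: float = 0.1
    ring_decay_seconds: float = 4.0

    def __post_init__(self) -> None:
        if self.peak_time_seconds <= 0:
            raise InvalidArgumentError("peak_time_seconds must be positive")
        if self.dispersion_seconds <= 0:
            raise InvalidArgumentError("dispersion_seconds must be positive")
        if not (0.0 <= self.undershoot_ratio < 1.0):
            raise InvalidArgumentError("undershoot_ratio must be in [0, 1)")
        if self.undershoot_delay_seconds <= 0:
            raise InvalidArgumentError("undershoot_delay_seconds must be positive")
        if self.ring_amplitude_percent < 0 or self.ring_frequency_hz < 0:
            raise InvalidArgumentError("ring amplitude/frequency must be >= 0")
        if self.ring_decay_seconds <= 0:
            raise InvalidArgumentError("ring_decay_seconds must be positive")

    @property
    def undershoot_width(self) -> float:
        if self.undershoot_dispersion_seconds is not None:
            return self.undershoot_dispersion_seconds
        return 1.6 * self.dispersion_seconds


@dataclass(frozen=True)
class NoiseModel:
    """Additive noise and drift for simulated runs.

    All-zero amplitudes give a deterministic noiseless run; a fixed seed
    gives bit-identical output. ``rician_floor`` > 0 switches the
    measurement to the magnitude of a complex Gaussian (non-Gaussian noise),
    with the floor expressed in percent of baseline on the quadrature
    channel.
    """

    white_sd_percent: float = 0.0
    ar1_coefficient: float = 0.0
    drift_amplitude_percent: float = 0.0
    drift_period_seconds: float = 120.0
    linear_drift_percent: float = 0.0
    rician_floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.white_sd_percent < 0:
            raise InvalidArgumentError("white_sd_percent must be >= 0")
        if not (-1.0 < self.ar1_coefficient < 1.0):
            raise InvalidArgumentError("ar1_coefficient must be in (-1, 1)")
        if self.drift_amplitude_percent < 0 or self.rician_floor < 0:
            raise InvalidArgumentError("drift/rician amplitudes must be >= 0")
        if self.drift_period_seconds <= 0:
            raise InvalidArgumentError("drift_period_seconds must be positive")


def cortical_model(amplitude_percent: float = 1.2) -> HrfModel:
    """Typical early-visual-cortex response: slower peak, clear undershoot."""
    return HrfModel(
        amplitude_percent=amplitude_percent,
        peak_time_seconds=6.5,
        dispersion_seconds=2.0,
        undershoot_ratio=0.3,
        undershoot_delay_seconds=9.0,
    )


def subcortical_model(amplitude_percent: float = 0.8, ringing: bool = False) -> HrfModel:
    """Typical subcortical-nucleus response: faster, narrower, no undershoot,
    optional post-peak ringing."""
    return HrfModel(
        amplitude_percent=amplitude_percent,
        peak_time_seconds=5.0,
        dispersion_seconds=1.5,
        undershoot_ratio=0.0,
        ring_amplitude_percent=0.15 * amplitude_percent if ringing else 0.0,
        ring_frequency_hz=0.12,
        ring_decay_seconds=5.0,
    )


# ---------------------------------------------------------------------------
# continuous model
# ---------------------------------------------------------------------------


def _gamma_lobe(t: np.ndarray, peak: float, width: float) -> np.ndarray:
    """Gamma variate with unit peak at ``peak``; ``width`` ~ Gaussian sigma."""
    a = (peak / width) ** 2
    out = np.zeros_like(t, dtype=float)
    pos = t > 0
    tp = t[pos] / peak
    # log-domain to avoid overflow for large shape parameters
    out[pos] = np.exp(a * (np.log(tp) + 1.0 - tp))
    return out


def make_hrf_kernel(model: HrfModel, dt: float, duration: float) -> np.ndarray:
    """Sample the continuous HRF kernel on a uniform grid.

    Returns ``floor(duration/dt) + 1`` samples at times ``0, dt, ...``; the
    first sample is exactly zero. Peak of the positive lobe equals
    ``amplitude_percent`` when undershoot and ringing are absent.
    """
    if dt <= 0 or duration <= 0:
        raise InvalidArgumentError("dt and duration must be positive")
    if duration < model.peak_time_seconds:
        raise InvalidArgumentError("duration must cover peak_time_seconds")
    n = int(math.floor(duration / dt + 1e-9)) + 1
    t = np.arange(n) * dt
    amp = model.amplitude_percent
    curve = amp * _gamma_lobe(t, model.peak_time_seconds, model.dispersion_seconds)
    if model.undershoot_ratio > 0 and amp != 0:
        curve -= (
            model.undershoot_ratio
            * amp
            * _gamma_lobe(
                t,
                model.peak_time_seconds + model.undershoot_delay_seconds,
                model.undershoot_width,
            )
        )
    if model.ring_amplitude_percent > 0:
        rel = t - model.peak_time_seconds
        late = rel > 0
        ring = np.zeros_like(t)
        ring[late] = (
            model.ring_amplitude_percent
            * np.exp(-rel[late] / model.ring_decay_seconds)
            * np.sin(2 * np.pi * model.ring_frequency_hz * rel[late])
        )
        curve += ring
    curve[0] = 0.0
    return curve


def trial_response(
    model: HrfModel,
    stim_duration: float,
    dt: float = _FINE_DT,
    duration: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-trial response: kernel averaged over the stimulus boxcar.

    The result is rescaled so its maximum equals ``amplitude_percent``
    exactly (ground truth stays literal despite the boxcar smearing).
    Returns ``(times, response)`` on the fine grid.
    """
    if duration is None:
        duration = model.peak_time_seconds + model.undershoot_delay_seconds + 40.0
    kernel = make_hrf_kernel(model, dt, duration)
    n_box = max(1, int(round(stim_duration / dt)))
    box = np.full(n_box, 1.0 / n_box)
    resp = np.convolve(kernel, box)[: kernel.size]
    peak = resp.max()
    if peak > 0:
        resp *= model.amplitude_percent / peak
    t = np.arange(kernel.size) * dt
    return t, resp


def evaluate_train(
    times: np.ndarray, acq: AcquisitionSpec, model: HrfModel
) -> np.ndarray:
    """Evaluate the superposed trial-response train at arbitrary times
    (percent units), relative to the run start."""
    ft, resp = trial_response(model, acq.stim_duration_seconds)
    times = np.asarray(times, dtype=float)
    out = np.zeros_like(times)
    for onset in acq.trial_onsets_seconds():
        rel = times - onset
        out += np.interp(rel, ft, resp, left=0.0, right=0.0)
    return out


# ---------------------------------------------------------------------------
# run-level simulation
# ---------------------------------------------------------------------------


def _noise_percent(
    n: int, tr: float, noise: NoiseModel, rng: np.random.Generator
) -> np.ndarray:
    """Drift + AR(1) noise in percent units (no Rician component)."""
    t = np.arange(n) * tr
    out = np.zeros(n)
    phase = rng.uniform(0.0, 2 * np.pi)
    if noise.drift_amplitude_percent > 0:
        out += noise.drift_amplitude_percent * np.cos(
            2 * np.pi * t / noise.drift_period_seconds + phase
        )
    if noise.linear_drift_percent != 0:
        out += noise.linear_drift_percent * (t / max(t[-1], tr) - 0.5)
    w = rng.standard_normal(n)
    if noise.white_sd_percent > 0:
        rho = noise.ar1_coefficient
        e = np.empty(n)
        e[0] = w[0]
        if rho != 0.0:
            scale = math.sqrt(1.0 - rho * rho)
            for i in range(1, n):
                e[i] = rho * e[i - 1] + scale * w[i]
        else:
            e = w
        out += noise.white_sd_percent * e
    return out


def simulate_roi_run(
    acq: AcquisitionSpec,
    model: HrfModel,
    noise: NoiseModel,
    baseline_intensity: float = 1000.0,
    rng: np.random.Generator | None = None,
) -> RunSeries:
    """Simulate one run of a single ROI's mean time series (raw units).

    With all noise amplitudes zero the output is exactly
    ``baseline * (1 + train/100)``. The ground-truth model travels in
    ``meta['truth']`` so recovery tests can compare estimates to it.
    """
    if baseline_intensity <= 0:
        raise InvalidArgumentError("baseline_intensity must be positive")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    times = acq.volume_times()
    signal = evaluate_train(times, acq, model)
    pct = signal + _noise_percent(times.size, acq.tr_seconds, noise, rng)
    raw = baseline_intensity * (1.0 + pct / 100.0)
    if noise.rician_floor > 0:
        sigma = noise.white_sd_percent / 100.0 * baseline_intensity
        imag = (
            noise.rician_floor / 100.0 * baseline_intensity
            + sigma * rng.standard_normal(times.size)
        )
        raw = np.sqrt(raw**2 + imag**2)
    return RunSeries(
        values=raw,
        tr_seconds=acq.tr_seconds,
        units="raw",
        meta={"truth": model, "noise": noise, "baseline": baseline_intensity},
    )


def simulate_session(
    acq: AcquisitionSpec,
    model: HrfModel,
    noise: NoiseModel,
    baseline_intensity: float = 1000.0,
    seed: int | None = None,
) -> list[RunSeries]:
    """Simulate all ``acq.n_runs`` runs of a session with independent noise."""
    root = np.random.default_rng(noise.seed if seed is None else seed)
    return [
        simulate_roi_run(acq, model, noise, baseline_intensity, rng=rng)
        for rng in root.spawn(acq.n_runs)
    ]


def simulate_volume_run(
    acq: AcquisitionSpec,
    roi_masks: np.ndarray,
    per_roi_models: dict[int, HrfModel],
    noise: NoiseModel,
    baseline_intensity: float = 1000.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a 4-D run (x, y, slice, time) from an integer label volume.

    Slice-dependent acquisition offsets are honored by sampling the
    continuous model at ``volume_time + slice_offset``, so slice-timing
    correction can be validated end to end. Label 0 is background (no
    signal). Noise is drawn independently per voxel.
    """
    labels = np.asarray(roi_masks)
    if labels.ndim != 3:
        raise InvalidArgumentError("roi_masks must be a 3-D label volume")
    if labels.shape[2] != acq.n_slices:
        raise InvalidArgumentError(
            f"mask has {labels.shape[2]} slices, acquisition expects {acq.n_slices}"
        )
    present = set(np.unique(labels)) - {0}
    unknown = present - set(per_roi_models)
    if unknown:
        raise ConfigurationError(f"mask labels without a model: {sorted(unknown)}")
    if rng is None:
        rng = np.random.default_rng(noise.seed)

    nt = acq.volumes_per_run
    times = acq.volume_times()
    data = np.empty(labels.shape + (nt,), dtype=float)
    # percent signal per (label, slice), shared by voxels of that pair
    for z in range(acq.n_slices):
        t_acq = times + acq.slice_offsets[z]
        for lab in present | {0}:
            vox = labels[:, :, z] == lab
            if not vox.any():
                continue
            if lab == 0:
                sig = np.zeros(nt)
            else:
                sig = evaluate_train(t_acq, acq, per_roi_models[lab])
            data[vox, z, :] = sig
    # per-voxel independent noise
    flat = data.reshape(-1, nt)
    for i in range(flat.shape[0]):
        pct = flat[i] + _noise_percent(nt, acq.tr_seconds, noise, rng)
        raw = baseline_intensity * (1.0 + pct / 100.0)
        if noise.rician_floor > 0:
            sigma = noise.white_sd_percent / 100.0 * baseline_intensity
            imag = (
                noise.rician_floor / 100.0 * baseline_intensity
                + sigma * rng.standard_normal(nt)
            )
            raw = np.sqrt(raw**2 + imag**2)
        flat[i] = raw
    return flat.reshape(labels.shape + (nt,)), labels


def simulate_epochs(
    acq: AcquisitionSpec,
    model: HrfModel,
    noise_sd_percent: float,
    rng: np.random.Generator | int = 0,
    n_epochs: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw single-trial epochs directly: truth + white noise, percent units.

    Shortcut for statistical-calibration studies where the run-level drift
    and raw-unit plumbing are irrelevant. Returns ``(epochs, truth)`` with
    ``epochs`` of shape ``(n_epochs, samples_per_trial)``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if n_epochs is None:
        n_epochs = acq.epochs_per_session
    ft, resp = trial_response(model, acq.stim_duration_seconds)
    t = np.arange(acq.samples_per_trial) * acq.tr_seconds
    truth = np.interp(t, ft, resp, left=0.0, right=0.0)
    epochs = truth + noise_sd_percent * rng.standard_normal(
        (n_epochs, acq.samples_per_trial)
    )
    return epochs, truth


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_session_tsv(
    runs: list[RunSeries], path: str | Path, roi_label: str = "roi"
) -> None:
    """Write runs as TSV (time_seconds + one column per run) with a JSON
    ground-truth sidecar."""
    import pandas as pd

    path = Path(path)
    n = min(len(r) for r in runs)
    frame = {"time_seconds": np.arange(n) * runs[0].tr_seconds}
    for i, r in enumerate(runs):
        frame[f"{roi_label}_run{i + 1}"] = r.values[:n]
    pd.DataFrame(frame).to_csv(path, sep="\t", index=False, float_format="%.10g")
    truth = runs[0].meta.get("truth")
    sidecar = {
        "tr_seconds": runs[0].tr_seconds,
        "units": runs[0].units,
        "n_runs": len(runs),
        "truth": asdict(truth) if truth is not None else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def write_volume_nifti(
    data4d: np.ndarray, labels: np.ndarray, tr_seconds: float, prefix: str | Path
) -> tuple[Path, Path]:
    """Write a simulated 4-D run and its label mask as NIfTI-1, with the TR
    stored in the header time step."""
    import nibabel as nib

    prefix = Path(prefix)
    img = nib.Nifti1Image(np.asarray(data4d, dtype=np.float32), np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, tr_seconds))
    img.header.set_xyzt_units("mm", "sec")
    bold_path = prefix.with_name(prefix.name + "_bold.nii")
    nib.save(img, bold_path)
    mimg = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), np.eye(4))
    mask_path = prefix.with_name(prefix.name + "_mask.nii")
    nib.save(mimg, mask_path)
    return bold_path, mask_path
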