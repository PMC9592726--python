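"""Config-driven orchestration: simulate -> preprocess -> epoch -> bootstrap.

A :class:`PipelineConfig` fully determines every output byte (all random
draws are seeded). ``run_subject`` produces per-ROI epoch sets, HRF
descriptors and within-subject bootstrap results; ``run_group`` combines
subject reports into group curves, parameter histograms, the undershoot
test and pairwise comparisons.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .acquisition import PRESETS, AcquisitionSpec
from .bootstrap_stats import (
    BootstrapResult,
    GroupResult,
    bootstrap_across,
    bootstrap_within,
    compare_params,
)
from .epoching import EpochSet, baseline_adjust, extract_epochs
from .errors import ConfigurationError, InsufficientDataError
from .preprocess import preprocess_run
from .series import RunSeries
from .synthetic_data import HrfModel, NoiseModel, simulate_session, write_session_tsv

log = logging.getLogger("boldhrf")

__all__ = ["PipelineConfig", "SubjectReport", "GroupReport", "run_subject", "run_group"]


@dataclass
class PipelineConfig:
    """Everything needed to process (or simulate) one subject."""

    acquisition: AcquisitionSpec
    rois: dict[str, HrfModel]
    noise: NoiseModel = field(default_factory=NoiseModel)
    baseline_intensity: float = 1000.0
    kernel_duration_seconds: float | None = None  # default: trial period
    n_boot: int = 500
    seed: int = 0
    subject_id: str = "sub-01"
    field_strength_tesla: float = float("nan")
    input_tsv: dict[str, str] | None = None  # ROI -> session TSV (skip simulation)

    @property
    def kernel_duration(self) -> float:
        if self.kernel_duration_seconds is not None:
            return self.kernel_duration_seconds
        return self.acquisition.trial_period_seconds

    @classmethod
    def from_dict(cls, cfg: dict[str, Any]) -> "PipelineConfig":
        cfg = dict(cfg)
        if "preset" in cfg:
            preset = cfg.pop("preset")
            if preset not in PRESETS:
                raise ConfigurationError(
                    f"unknown preset {preset!r}; choose from {sorted(PRESETS)}"
                )
            kwargs = {}
            if "n_runs" in cfg:
                kwargs["n_runs"] = int(cfg.pop("n_runs"))
            acq = PRESETS[preset](**kwargs)
            field_t = 9.4 if preset == "9.4T" else 3.0
        elif "acquisition" in cfg:
            acq = AcquisitionSpec(**cfg.pop("acquisition"))
            field_t = float(cfg.pop("field_strength_tesla", float("nan")))
        else:
            raise ConfigurationError("config needs a 'preset' or an 'acquisition' block")
        rois = {
            name: HrfModel(**params) for name, params in cfg.pop("rois", {}).items()
        }
        if not rois and "input_tsv" not in cfg:
            raise ConfigurationError("config defines no ROIs and no input files")
        noise = NoiseModel(**cfg.pop("noise", {}))
        return cls(
            acquisition=acq,
            rois=rois,
            noise=noise,
            baseline_intensity=float(cfg.pop("baseline_intensity", 1000.0)),
            kernel_duration_seconds=cfg.pop("kernel_duration_seconds", None),
            n_boot=int(cfg.pop("n_boot", 500)),
            seed=int(cfg.pop("seed", 0)),
            subject_id=str(cfg.pop("subject_id", "sub-01")),
            field_strength_tesla=float(cfg.pop("field_strength_tesla", field_t)),
            input_tsv=cfg.pop("input_tsv", None),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class SubjectReport:
    subject_id: str
    field_strength_tesla: float
    epoch_sets: dict[str, EpochSet]
    results: dict[str, BootstrapResult]
    qc: dict[str, Any]


@dataclass
class GroupReport:
    groups: dict[str, GroupResult]
    comparisons: dict[str, float]
    undershoot_p: dict[str, float]


def _load_session_tsv(path: str | Path) -> list[RunSeries]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    side = json.loads(path.with_suffix(".json").read_text())
    tr = float(side["tr_seconds"])
    runs = []
    for col in df.columns:
        if col == "time_seconds":
            continue
        runs.append(RunSeries(df[col].to_numpy(float), tr, units=side.get("units", "raw")))
    return runs


def run_subject(
    config: PipelineConfig, outdir: str | Path | None = None
) -> SubjectReport:
    """Process one subject end to end; optionally write all stage outputs."""
    acq = config.acquisition
    rng_root = np.random.default_rng(config.seed)
    epoch_sets: dict[str, EpochSet] = {}
    results: dict[str, BootstrapResult] = {}
    qc: dict[str, Any] = {"rois": {}}

    roi_names = (
        list(config.input_tsv) if config.input_tsv else list(config.rois)
    )
    for roi in roi_names:
        if config.input_tsv and roi in config.input_tsv:
            runs = _load_session_tsv(config.input_tsv[roi])
        else:
            sim_seed = int(rng_root.integers(0, 2**31 - 1))
            runs = simulate_session(
                acq,
                config.rois[roi],
                config.noise,
                config.baseline_intensity,
                seed=sim_seed,
            )
            if outdir is not None:
                write_session_tsv(
                    runs, Path(outdir) / f"{config.subject_id}_{roi}_raw.tsv", roi
                )
        log.info("ROI %s: %d run(s) of %d volumes", roi, len(runs), len(runs[0]))
        processed = [preprocess_run(r, config.kernel_duration) for r in runs]
        es = baseline_adjust(
            extract_epochs(
                processed,
                acq,
                roi_label=roi,
                subject_id=config.subject_id,
                field_strength_tesla=config.field_strength_tesla,
            )
        )
        epoch_sets[roi] = es
        boot_seed = int(rng_root.integers(0, 2**31 - 1))
        res = bootstrap_within(es, n_boot=config.n_boot, seed=boot_seed)
        results[roi] = res
        qc["rois"][roi] = {
            "n_epochs": es.n_epochs,
            "cnr": res.cnr,
            "flags": res.flags,
        }
        if outdir is not None:
            outdir = Path(outdir)
            es.to_tsv(outdir / f"{config.subject_id}_{roi}_epochs.tsv")
            res.to_dir(outdir)
    if outdir is not None:
        (Path(outdir) / f"{config.subject_id}_qc.json").write_text(
            json.dumps(qc, indent=2, default=str)
        )
    return SubjectReport(
        subject_id=config.subject_id,
        field_strength_tesla=config.field_strength_tesla,
        epoch_sets=epoch_sets,
        results=results,
        qc=qc,
    )


def params_table(report: SubjectReport) -> pd.DataFrame:
    """Flat TSV-ready table of the subject's per-ROI HRF descriptors."""
    rows = []
    for roi, res in report.results.items():
        p = res.params
        rows.append(
            {
                "subject": report.subject_id,
                "roi": roi,
                "field_tesla": report.field_strength_tesla,
                "p_amp": None if p is None else p.p_amp,
                "ttp_seconds": None if p is None else p.ttp_seconds,
                "onset_seconds": None if p is None else p.onset_seconds,
                "fwhm_seconds": None if p is None else p.fwhm_seconds,
                "undershoot_amp": None if p is None else p.undershoot_amp,
                "cnr": res.cnr,
            }
        )
    return pd.DataFrame(rows)


def run_group(
    subject_reports: Sequence[SubjectReport],
    n_boot2: int = 2000,
    seed: int = 0,
    comparisons: Sequence[tuple[str, str, str]] = (),
    resample_to_common_grid: bool = False,
    outdir: str | Path | None = None,
) -> GroupReport:
    """Across-subject statistics per ROI, plus requested pairwise comparisons.

    ``comparisons`` entries are ``(roi_a, roi_b, param_name)``. Refuses to
    run with fewer than two subjects.
    """
    reports = list(subject_reports)
    if len(reports) < 2:
        raise InsufficientDataError("group statistics need >= 2 subjects")
    rois = list(reports[0].results)
    rng = np.random.default_rng(seed)
    groups: dict[str, GroupResult] = {}
    undershoot_p: dict[str, float] = {}
    for roi in rois:
        subject_results = [r.results[roi] for r in reports if roi in r.results]
        g = bootstrap_across(
            subject_results,
            n_boot2=n_boot2,
            seed=int(rng.integers(0, 2**31 - 1)),
            resample_to_common_grid=resample_to_common_grid,
        )
        groups[roi] = g
        undershoot_p[roi] = g.p_undershoot
    comps: dict[str, float] = {}
    for roi_a, roi_b, name in comparisons:
        if roi_a not in groups or roi_b not in groups:
            raise ConfigurationError(f"comparison references unknown ROI: {roi_a}, {roi_b}")
        comps[f"{roi_a}_vs_{roi_b}:{name}"] = compare_params(
            groups[roi_a], groups[roi_b], name
        )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for roi, g in groups.items():
            g.curve_frame().to_csv(
                outdir / f"group_{roi}_curve.tsv",
                sep="\t",
                index=False,
                float_format="%.10g",
            )
            g.param_samples.to_csv(
                outdir / f"group_{roi}_param_samples.tsv",
                sep="\t",
                index=False,
                float_format="%.10g",
            )
        (outdir / "group_report.json").write_text(
            json.dumps(
                {
                    "undershoot_p": undershoot_p,
                    "comparisons": comps,
                    "n_boot2": n_boot2,
                    "seed": seed,
                    "subjects": [r.subject_id for r in reports],
                },
                indent=2,
            )
        )
    return GroupReport(groups=groups, comparisons=comps, undershoot_p=undershoot_p)
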