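"""Study vocabulary and the generative parameterization of the synthetic cohort.

The synthetic cohort mirrors a scan-rescan volumetry study design: each
participant contributes several T1-weighted scans, every scan is pushed
through a step-wise pre-processing pipeline several times, and six regional
volumes plus a total brain volume (TBV) are extracted after every step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import yaml

#: Pre-processing steps, in pipeline order: native space (ORIG), rigid-body
#: rotation to template (RROT), N4 bias-field correction (N4BC),
#: skull-stripping with its internal bias correction (N4SS), and the
#: self-contained FreeSurfer pipeline (FS).
STEPS: tuple[str, ...] = ("ORIG", "RROT", "N4BC", "N4SS", "FS")

#: Regions of interest: bilateral putamen, hippocampus, middle temporal gyrus.
ROIS: tuple[str, ...] = ("LPut", "RPut", "LHip", "RHip", "LMTG", "RMTG")

#: E|X| for X ~ N(0, 1) folded, times 2: the small-sigma constant linking a
#: log-scale scan noise sigma to the expected percent variability error,
#: PVE ~= 100 * (2/sqrt(pi)) * sigma.
HALF_NORMAL_FACTOR: float = 2.0 / math.sqrt(math.pi)

# Per-cell target percent variability errors (percent of TBV) used to
# calibrate the default scan noise. Magnitudes span the 1-3.7% range typical
# of scan-rescan variability in registration-based pipelines, increasing
# from native-space processing to skull-stripping.
_TARGET_PVE: dict[str, dict[str, float]] = {
    "ORIG": {"LPut": 1.00, "RPut": 1.14, "LHip": 1.36, "RHip": 1.17, "LMTG": 1.40, "RMTG": 1.18},
    "RROT": {"LPut": 1.40, "RPut": 1.31, "LHip": 1.51, "RHip": 1.41, "LMTG": 1.56, "RMTG": 1.43},
    "N4BC": {"LPut": 1.48, "RPut": 1.43, "LHip": 1.51, "RHip": 1.46, "LMTG": 1.60, "RMTG": 1.45},
    "N4SS": {"LPut": 3.41, "RPut": 3.26, "LHip": 3.37, "RHip": 3.55, "LMTG": 3.64, "RMTG": 3.71},
    "FS": {"LPut": 2.42, "RPut": 2.41, "LHip": 2.35, "RHip": 1.86, "LMTG": 3.09, "RMTG": 2.58},
}

# Mean regional fractions of TBV for healthy young adults (putamen ~4.6 cm3,
# hippocampus ~3.4 cm3, middle temporal gyrus ~14 cm3 against a ~1.5 L brain).
_DEFAULT_BASE_RATIO: dict[str, float] = {
    "LPut": 0.0031,
    "RPut": 0.0030,
    "LHip": 0.0022,
    "RHip": 0.0023,
    "LMTG": 0.0092,
    "RMTG": 0.0090,
}

# Multiplicative step biases relative to ORIG, carrying both a step main
# effect and a step-by-ROI interaction (skull-stripping and FreeSurfer act
# differently on cortical vs subcortical regions). Magnitudes are in the
# 1-4% range where volumetric group differences are conventionally read as
# meaningful.
_DEFAULT_STEP_BIAS: dict[str, dict[str, float]] = {
    "ORIG": {r: 1.000 for r in ROIS},
    "RROT": {"LPut": 0.985, "RPut": 0.985, "LHip": 0.983, "RHip": 0.983, "LMTG": 0.988, "RMTG": 0.987},
    "N4BC": {"LPut": 0.982, "RPut": 0.982, "LHip": 0.979, "RHip": 0.980, "LMTG": 0.989, "RMTG": 0.988},
    "N4SS": {"LPut": 1.001, "RPut": 1.001, "LHip": 1.001, "RHip": 1.001, "LMTG": 1.004, "RMTG": 1.003},
    "FS": {"LPut": 1.002, "RPut": 1.006, "LHip": 1.040, "RHip": 1.035, "LMTG": 1.020, "RMTG": 1.015},
}


def _default_scan_noise() -> dict[str, dict[str, float]]:
    return {
        step: {roi: pve / 100.0 / HALF_NORMAL_FACTOR for roi, pve in by_roi.items()}
        for step, by_roi in _TARGET_PVE.items()
    }


def _default_tbv_step_bias() -> dict[str, float]:
    # FreeSurfer's brain mask is systematically tighter than the
    # registration-based extraction mask.
    return {"ORIG": 1.0, "RROT": 1.0, "N4BC": 1.0, "N4SS": 1.0, "FS": 0.97}


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative parameterization of the synthetic cohort.

    Volumes are multiplicative log-normal: a per-participant TBV, a
    per-(participant, ROI) ratio deviation, a per-(step, ROI) bias, scan
    noise drawn once per scan, and run noise drawn once per pipeline run.

    Parameters
    ----------
    n_participants, n_scans, n_runs
        Cohort size, scans per participant, and repeated pipeline runs.
    steps, rois
        Ordered label vocabularies. Defaults are the five pipeline steps and
        six bilateral ROIs of the study design.
    tbv_mean, tbv_sd
        Mean and between-subject SD of total brain volume, mm^3.
    base_ratio
        Mean ROI volume as a fraction of TBV, per ROI.
    subject_sd
        Log-scale SD of the stable per-(participant, ROI) ratio deviation.
    step_bias
        Multiplicative bias per (step, ROI); carries the step main effect
        and the step-by-ROI interaction. Missing entries default to 1.
    scan_noise_sd
        Log-scale scan noise SD per (step, ROI), drawn once per scan and
        shared by all runs of that scan. Missing entries default to 0.
    run_noise_sd
        Log-scale run noise SD per step, drawn per pipeline run; 0 by
        default because repeated runs of a deterministic pipeline are
        statistically identical.
    tbv_step_bias
        Multiplicative factor on the recorded TBV per step (each pipeline
        derives its own brain mask). Missing entries default to 1.
    seed
        Root seed; all random substreams derive from it deterministically.
    """

    n_participants: int = 115
    n_scans: int = 3
    n_runs: int = 5
    steps: tuple[str, ...] = STEPS
    rois: tuple[str, ...] = ROIS
    tbv_mean: float = 1_513_592.0
    tbv_sd: float = 120_000.0
    base_ratio: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_BASE_RATIO))
    subject_sd: float = 0.08
    step_bias: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {s: dict(r) for s, r in _DEFAULT_STEP_BIAS.items()}
    )
    scan_noise_sd: Mapping[str, Mapping[str, float]] = field(default_factory=_default_scan_noise)
    run_noise_sd: Mapping[str, float] = field(default_factory=dict)
    tbv_step_bias: Mapping[str, float] = field(default_factory=_default_tbv_step_bias)
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("n_participants", "n_scans", "n_runs"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if len(self.steps) < 1 or len(self.rois) < 1:
            raise ValueError("steps and rois must be non-empty")
        if len(set(self.steps)) != len(self.steps) or len(set(self.rois)) != len(self.rois):
            raise ValueError("duplicate step or ROI labels")
        if self.tbv_mean <= 0:
            raise ValueError("tbv_mean must be strictly positive")
        if self.tbv_sd < 0 or self.subject_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        missing = set(self.rois) - set(self.base_ratio)
        if missing:
            raise ValueError(f"base_ratio missing ROIs: {sorted(missing)}")
        for roi, r in self.base_ratio.items():
            self._check_roi(roi, "base_ratio")
            if not 0 < r < 1:
                raise ValueError(f"base_ratio[{roi}] must lie in (0, 1), got {r}")
        for step, by_roi in self.step_bias.items():
            self._check_step(step, "step_bias")
            for roi, b in by_roi.items():
                self._check_roi(roi, f"step_bias[{step}]")
                if b <= 0:
                    raise ValueError(f"step_bias[{step}][{roi}] must be > 0, got {b}")
        for step, by_roi in self.scan_noise_sd.items():
            self._check_step(step, "scan_noise_sd")
            for roi, s in by_roi.items():
                self._check_roi(roi, f"scan_noise_sd[{step}]")
                if s < 0:
                    raise ValueError(f"scan_noise_sd[{step}][{roi}] must be >= 0, got {s}")
        for step, s in self.run_noise_sd.items():
            self._check_step(step, "run_noise_sd")
            if s < 0:
                raise ValueError(f"run_noise_sd[{step}] must be >= 0, got {s}")
        for step, b in self.tbv_step_bias.items():
            self._check_step(step, "tbv_step_bias")
            if b <= 0:
                raise ValueError(f"tbv_step_bias[{step}] must be > 0, got {b}")

    def _check_step(self, step: str, where: str) -> None:
        if step not in self.steps:
            raise ValueError(f"unknown step label {step!r} in {where}")

    def _check_roi(self, roi: str, where: str) -> None:
        if roi not in self.rois:
            raise ValueError(f"unknown ROI label {roi!r} in {where}")

    # -- parameter lookups with structural defaults ------------------------

    def step_bias_at(self, step: str, roi: str) -> float:
        return float(self.step_bias.get(step, {}).get(roi, 1.0))

    def scan_sigma_at(self, step: str, roi: str) -> float:
        return float(self.scan_noise_sd.get(step, {}).get(roi, 0.0))

    def run_sigma_at(self, step: str) -> float:
        return float(self.run_noise_sd.get(step, 0.0))

    def tbv_bias_at(self, step: str) -> float:
        return float(self.tbv_step_bias.get(step, 1.0))

    # -- convenience constructors ------------------------------------------

    @classmethod
    def noise_free(cls, **overrides) -> "SimulationConfig":
        """Config with all noise at 0 and all biases at 1 (ideal pipeline)."""
        base = dict(
            tbv_sd=0.0,
            subject_sd=0.0,
            step_bias={},
            scan_noise_sd={},
            run_noise_sd={},
            tbv_step_bias={},
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def null_effects(cls, **overrides) -> "SimulationConfig":
        """Default noise structure but no step effect anywhere (global null)."""
        base = dict(step_bias={}, tbv_step_bias={})
        base.update(overrides)
        return cls(**base)

    def with_(self, **overrides) -> "SimulationConfig":
        return replace(self, **overrides)

    # -- YAML round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "n_scans": self.n_scans,
            "n_runs": self.n_runs,
            "steps": list(self.steps),
            "rois": list(self.rois),
            "tbv_mean": float(self.tbv_mean),
            "tbv_sd": float(self.tbv_sd),
            "base_ratio": {k: float(v) for k, v in self.base_ratio.items()},
            "subject_sd": float(self.subject_sd),
            "step_bias": {s: {r: float(b) for r, b in m.items()} for s, m in self.step_bias.items()},
            "scan_noise_sd": {s: {r: float(v) for r, v in m.items()} for s, m in self.scan_noise_sd.items()},
            "run_noise_sd": {s: float(v) for s, v in self.run_noise_sd.items()},
            "tbv_step_bias": {s: float(v) for s, v in self.tbv_step_bias.items()},
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        for key in ("steps", "rois"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
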