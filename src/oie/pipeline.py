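"""End-to-end workflow: simulate -> process -> fit -> predict -> compare.

Each stage reads and writes plain CSV/JSON under a run directory and is
recorded in a manifest with content checksums, so a rerun with the same
configuration and seed reproduces identical data files.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import CoactivationTable, TrialSeries, all_conditions
from .identify import (
    IdentificationConfig,
    IdentificationResult,
    aicc_compare,
    alternate_fit,
)
from .model import (
    EffectiveNoise,
    IDENTIFIED_NOISE,
    OieParams,
    predict_surface,
)
from .signals import normalize_coactivation, trial_metrics
from .synthetic import TrialConfig, generate_study
from .tem import fit_tem_ratio

ALL_STAGES = ("simulate", "process", "fit", "predict", "compare")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    gamma: float = OieParams().gamma
    effective_noise: EffectiveNoise = IDENTIFIED_NOISE
    trials_per_condition: int = 9
    observation_noise_sd: float = 0.02
    trial_config: TrialConfig = TrialConfig()
    identification: IdentificationConfig = IdentificationConfig()
    k_oie: int = 7
    k_tem: int = 2

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "effective_noise" in kwargs:
            en = kwargs["effective_noise"]
            kwargs["effective_noise"] = EffectiveNoise(
                tuple(en["sigma_v"]), tuple(en["sigma_h"])
            )
        if "trial_config" in kwargs:
            kwargs["trial_config"] = TrialConfig(**kwargs["trial_config"])
        if "identification" in kwargs:
            kwargs["identification"] = IdentificationConfig(**kwargs["identification"])
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        return cls(**kwargs)

    def canonical(self) -> dict:
        return {
            "seed": self.seed,
            "stages": list(self.stages),
            "gamma": self.gamma,
            "sigma_v": list(self.effective_noise.sigma_v),
            "sigma_h": list(self.effective_noise.sigma_h),
            "trials_per_condition": self.trials_per_condition,
            "observation_noise_sd": self.observation_noise_sd,
            "duration": self.trial_config.duration,
            "sample_rate": self.trial_config.sample_rate,
            "identification_seed": self.identification.seed,
            "k_oie": self.k_oie,
            "k_tem": self.k_tem,
        }


@dataclass
class RunManifest:
    """Provenance record: config hash, outputs with checksums, stamps."""

    config_hash: str
    version: str
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, outputs: dict[str, Path]) -> None:
        self.stages[stage] = {
            "outputs": {name: _sha256(p) for name, p in outputs.items()},
            "paths": {name: str(p) for name, p in outputs.items()},
            "completed_at": _time.strftime("%Y-%m-%dT%H:%M:%S"),
        }

    def write(self, path: Path) -> None:
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(asdict(self), indent=2) + "\n")
        tmp.replace(path)  # atomic on POSIX


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def validate_table(path: str | Path, value_name: str = "u_n") -> CoactivationTable:
    """Load and schema-check a condition coactivation table.

    Requires exactly the nine visual x haptic conditions, no
    duplicates, finite non-negative values.
    """
    frame = pd.read_csv(path)
    table = CoactivationTable.from_frame(frame, value_name)
    if np.any(table.values < 0):
        raise ValueError("coactivation values must be non-negative")
    return table


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in order under ``config.out_dir``."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    config_hash = hashlib.sha256(
        json.dumps(config.canonical(), sort_keys=True).encode()
    ).hexdigest()
    from . import __version__

    manifest = RunManifest(config_hash=config_hash, version=__version__)
    manifest_path = out / "manifest.json"
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        try:
            outputs = _STAGE_FUNCS[stage](config, out)
        except Exception as exc:  # fail fast, tagged with the stage
            raise StageError(f"stage '{stage}' failed: {exc}") from exc
        manifest.record(stage, outputs)
        manifest.write(manifest_path)
    return manifest


def _stage_simulate(config: RunConfig, out: Path) -> dict[str, Path]:
    study = generate_study(
        oie_params=OieParams(gamma=config.gamma),
        effective_noise=config.effective_noise,
        trials_per_condition=config.trials_per_condition,
        observation_noise_sd=config.observation_noise_sd,
        seed=config.seed,
        trial_config=config.trial_config,
    )
    trials_dir = out / "trials"
    trials_dir.mkdir(exist_ok=True)
    outputs: dict[str, Path] = {}
    for cond in study.conditions:
        for k, trial in enumerate(study.trials[cond.label]):
            p = trials_dir / f"{cond.label}_trial{k:02d}.csv"
            trial.to_csv(p)
            outputs[f"trial_{cond.label}_{k:02d}"] = p
    table_path = out / "coactivation.csv"
    study.coactivation_observed.to_csv(table_path)
    truth_path = out / "coactivation_truth.csv"
    study.coactivation_truth.to_csv(truth_path)
    outputs["coactivation"] = table_path
    outputs["coactivation_truth"] = truth_path
    return outputs


def _stage_process(config: RunConfig, out: Path) -> dict[str, Path]:
    trials_dir = out / "trials"
    paths = sorted(trials_dir.glob("*_trial*.csv"))
    if not paths:
        raise FileNotFoundError(f"no trial CSVs under {trials_dir}")
    rows = []
    for p in paths:
        label = p.stem.split("_trial")[0]
        trial = TrialSeries.from_csv(p)
        m = trial_metrics(trial)
        rows.append(
            {
                "trial_id": p.stem,
                "condition": label,
                "e_deg": m.tracking_error,
                "mean_coact_nm": m.mean_coactivation,
            }
        )
    frame = pd.DataFrame(rows)
    frame["u_n"] = normalize_coactivation(frame["mean_coact_nm"].to_numpy())
    metrics_path = out / "metrics.csv"
    frame.to_csv(metrics_path, index=False, float_format="%.12g")
    return {"metrics": metrics_path}


def _stage_fit(config: RunConfig, out: Path) -> dict[str, Path]:
    table = validate_table(out / "coactivation.csv")
    result = alternate_fit(table.values, config.identification)
    fit_path = out / "fit.json"
    result.to_json(fit_path)
    return {"fit": fit_path}


def _load_fit(out: Path) -> IdentificationResult:
    raw = json.loads((out / "fit.json").read_text())
    return IdentificationResult(
        effective_noise=EffectiveNoise(tuple(raw["sigma_v"]), tuple(raw["sigma_h"])),
        gamma_star=raw["gamma_star"],
        kkt_residual=raw["kkt_residual"],
        n_restarts_agreeing=raw["n_restarts_agreeing"],
        rounds=raw["rounds"],
        converged=raw["converged"],
        seed=raw["seed"],
    )


def _stage_predict(config: RunConfig, out: Path) -> dict[str, Path]:
    fit = _load_fit(out)
    surface = predict_surface(fit.effective_noise, fit.gamma_star)
    normalized = surface.normalized()
    frame = surface.to_frame()
    frame["u_star_normalized"] = normalized.to_frame()["u_star"]
    surface_path = out / "surface.csv"
    frame.to_csv(surface_path, index=False, float_format="%.12g")
    return {"surface": surface_path}


def _stage_compare(config: RunConfig, out: Path) -> dict[str, Path]:
    observed = validate_table(out / "coactivation.csv")
    fit = _load_fit(out)
    predicted = predict_surface(fit.effective_noise, fit.gamma_star)
    rss_oie = float(np.sum((predicted.values - observed.values) ** 2))
    metrics = pd.read_csv(out / "metrics.csv")
    error_table = (
        metrics.groupby("condition")["e_deg"].mean().reindex(
            [c.label for c in all_conditions()]
        ).to_numpy().reshape(3, 3)
    )
    _, rss_tem = fit_tem_ratio(error_table, observed.values)
    comparison = aicc_compare(
        rss_oie, config.k_oie, rss_tem, config.k_tem, n=observed.values.size
    )
    cmp_path = out / "comparison.json"
    comparison.to_json(cmp_path)
    return {"comparison": cmp_path}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "process": _stage_process,
    "fit": _stage_fit,
    "predict": _stage_predict,
    "compare": _stage_compare,
}
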