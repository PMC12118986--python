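"""Shared data containers for the visuo-haptic coactivation pipeline.

Conventions used throughout the package: angles in degrees, torques in Nm,
times in seconds, flexion positive. Coactivation tables are 3x3 grids
indexed (visual level, haptic level) with levels ordered sharp -> weak ->
strong.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

VISUAL_LEVELS = ("V0", "V1", "V2")
HAPTIC_LEVELS = ("H0", "H1", "H2")

#: Physical noise magnitude attached to each level: visual cloud angular
#: deviation sigma_c in mm on screen, haptic perturbation amplitude
#: sigma_p in Nm.
SIGMA_C_BY_LEVEL = {"V0": 0.0, "V1": 21.32, "V2": 52.78}
SIGMA_P_BY_LEVEL = {"H0": 0.0, "H1": 0.08, "H2": 0.19}

TRIAL_CSV_COLUMNS = [
    "time_s",
    "target_deg",
    "wrist_deg",
    "coupling_nm",
    "perturb_nm",
    "flexor_env",
    "extensor_env",
]


@dataclass(frozen=True)
class NoiseCondition:
    """One cell of the 3x3 visual x haptic noise design."""

    visual_level: str
    haptic_level: str

    def __post_init__(self) -> None:
        if self.visual_level not in VISUAL_LEVELS:
            raise ValueError(f"unknown visual level {self.visual_level!r}")
        if self.haptic_level not in HAPTIC_LEVELS:
            raise ValueError(f"unknown haptic level {self.haptic_level!r}")

    @property
    def sigma_c(self) -> float:
        """Visual cloud angular deviation (mm on screen)."""
        return SIGMA_C_BY_LEVEL[self.visual_level]

    @property
    def sigma_p(self) -> float:
        """Haptic perturbation amplitude (Nm)."""
        return SIGMA_P_BY_LEVEL[self.haptic_level]

    @property
    def label(self) -> str:
        return f"{self.visual_level}{self.haptic_level}"


def all_conditions() -> list[NoiseCondition]:
    """The nine conditions in row-major (visual, haptic) order."""
    return [
        NoiseCondition(v, h) for v in VISUAL_LEVELS for h in HAPTIC_LEVELS
    ]


@dataclass
class TrialSeries:
    """Time-indexed record of one tracking trial.

    All series share the uniform time grid; EMG envelopes are
    non-negative calibrated activation values.
    """

    time: np.ndarray
    target_angle: np.ndarray
    wrist_angle: np.ndarray
    coupling_torque: np.ndarray
    perturbation_torque: np.ndarray
    flexor_envelope: np.ndarray
    extensor_envelope: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in (
            "target_angle",
            "wrist_angle",
            "coupling_torque",
            "perturbation_torque",
            "flexor_envelope",
            "extensor_envelope",
        ):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} does not match the time grid")
            setattr(self, name, arr)
        self.time = np.asarray(self.time, dtype=float)
        if np.any(self.flexor_envelope < 0) or np.any(self.extensor_envelope < 0):
            raise ValueError("EMG envelopes must be non-negative")

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.time)))

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "target_deg": self.target_angle,
                "wrist_deg": self.wrist_angle,
                "coupling_nm": self.coupling_torque,
                "perturb_nm": self.perturbation_torque,
                "flexor_env": self.flexor_envelope,
                "extensor_env": self.extensor_envelope,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrialSeries":
        missing = set(TRIAL_CSV_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"trial table missing columns {sorted(missing)}")
        return cls(
            time=frame["time_s"].to_numpy(float),
            target_angle=frame["target_deg"].to_numpy(float),
            wrist_angle=frame["wrist_deg"].to_numpy(float),
            coupling_torque=frame["coupling_nm"].to_numpy(float),
            perturbation_torque=frame["perturb_nm"].to_numpy(float),
            flexor_envelope=frame["flexor_env"].to_numpy(float),
            extensor_envelope=frame["extensor_env"].to_numpy(float),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialSeries":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class CoactivationTable:
    """3x3 grid of coactivation values indexed (visual, haptic).

    ``values[i, j]`` is the entry for visual level ``VISUAL_LEVELS[i]``
    and haptic level ``HAPTIC_LEVELS[j]``. Depending on provenance the
    entries are trial-mean coactivation (Nm), normalized coactivation
    in [0, 1], or model-predicted optima.
    """

    values: np.ndarray
    value_name: str = "u_n"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (3, 3):
            raise ValueError("coactivation table must be 3x3")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("coactivation table contains non-finite values")

    def __getitem__(self, condition: NoiseCondition) -> float:
        i = VISUAL_LEVELS.index(condition.visual_level)
        j = HAPTIC_LEVELS.index(condition.haptic_level)
        return float(self.values[i, j])

    def __iter__(self) -> Iterator[tuple[NoiseCondition, float]]:
        for cond in all_conditions():
            yield cond, self[cond]

    def normalized(self) -> "CoactivationTable":
        """Min-max rescale the nine entries onto [0, 1]."""
        lo, hi = self.values.min(), self.values.max()
        if hi == lo:
            raise ValueError("degenerate table: all entries equal")
        return CoactivationTable((self.values - lo) / (hi - lo), self.value_name)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "visual_level": c.visual_level,
                "haptic_level": c.haptic_level,
                self.value_name: v,
            }
            for c, v in self
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, value_name: str = "u_n"
    ) -> "CoactivationTable":
        values = np.full((3, 3), np.nan)
        seen = set()
        for _, row in frame.iterrows():
            key = (str(row["visual_level"]), str(row["haptic_level"]))
            if key in seen:
                raise ValueError(f"duplicate condition {key[0]}{key[1]}")
            seen.add(key)
            try:
                i = VISUAL_LEVELS.index(key[0])
                j = HAPTIC_LEVELS.index(key[1])
            except ValueError as exc:
                raise ValueError(f"unknown condition {key[0]}{key[1]}") from exc
            values[i, j] = float(row[value_name])
        if np.any(np.isnan(values)):
            missing = [
                f"{VISUAL_LEVELS[i]}{HAPTIC_LEVELS[j]}"
                for i, j in zip(*np.nonzero(np.isnan(values)))
            ]
            raise ValueError(f"missing conditions: {missing}")
        return cls(values, value_name)

    @classmethod
    def from_csv(cls, path: str | Path, value_name: str = "u_n") -> "CoactivationTable":
        return cls.from_frame(pd.read_csv(path), value_name)
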