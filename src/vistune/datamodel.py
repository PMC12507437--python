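"""Core domain types for trial-level drifting-grating recordings.

The unit of raw data is one presentation of a drifting sinusoidal grating (or a
gray-screen blank of matched duration) together with a single unit's response on
that trial, expressed as a mean firing rate over the stimulus window.  Batteries
of conditions are distinguished by drift mode: back-and-forth gratings form the
orientation/spatial-frequency/contrast battery (B1), unidirectional gratings the
direction/temporal-frequency battery (B2).  Blanks inherit the drift-mode tag of
the battery they belong to so that each battery's "closest blank" is recoverable
from a flat trial table.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

GROUPS = ("control", "EO1contra", "EO1ipsi", "EO2")
HEMISPHERES = ("left", "right")
DRIFT_MODES = ("unidirectional", "back_and_forth")
CURVE_PARAMETERS = (
    "direction",
    "orientation",
    "spatial_frequency",
    "temporal_frequency",
    "contrast",
)


class ValidationError(ValueError):
    """A value violates a domain invariant."""


class SchemaError(ValueError):
    """A table is missing mandatory structure (columns, keys)."""


def battery_of(drift_mode: str) -> str:
    """Map a drift mode to its battery label ('B1' or 'B2')."""
    if drift_mode == "back_and_forth":
        return "B1"
    if drift_mode == "unidirectional":
        return "B2"
    raise ValidationError(f"unknown drift_mode {drift_mode!r}")


@dataclass(frozen=True)
class StimulusCondition:
    """One grating (or blank) stimulus.

    Directions are in degrees, 0 = upward drift, increasing clockwise.  For
    back-and-forth stimuli the direction modulo 180 (the orientation) is the
    informative quantity.  Blanks carry only duration and the battery tag.
    """

    kind: str  # "grating" | "blank"
    duration: float
    drift_mode: str = "unidirectional"
    direction: Optional[float] = None
    spatial_frequency: Optional[float] = None
    temporal_frequency: Optional[float] = None
    contrast: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("grating", "blank"):
            raise ValidationError(f"unknown stimulus kind {self.kind!r}")
        if self.drift_mode not in DRIFT_MODES:
            raise ValidationError(f"unknown drift_mode {self.drift_mode!r}")
        if not (self.duration > 0):
            raise ValidationError("duration must be > 0")
        if self.kind == "blank":
            for name in ("direction", "spatial_frequency", "temporal_frequency", "contrast"):
                if getattr(self, name) is not None:
                    raise ValidationError(f"blank condition must not carry {name}")
            return
        if self.direction is None or not (0 <= self.direction < 360):
            raise ValidationError("grating direction must lie in [0, 360)")
        if self.spatial_frequency is None or not (self.spatial_frequency > 0):
            raise ValidationError("spatial_frequency must be > 0")
        if self.temporal_frequency is None or not (self.temporal_frequency > 0):
            raise ValidationError("temporal_frequency must be > 0")
        if self.contrast is None or not (0 <= self.contrast <= 1):
            raise ValidationError("contrast must lie in [0, 1]")

    @property
    def is_blank(self) -> bool:
        return self.kind == "blank"

    @property
    def battery(self) -> str:
        return battery_of(self.drift_mode)

    @property
    def orientation(self) -> Optional[float]:
        if self.direction is None:
            return None
        return self.direction % 180.0


@dataclass(frozen=True)
class TrialObservation:
    """A single unit's response on a single stimulus presentation."""

    unit_id: str
    condition: StimulusCondition
    trial_index: int
    rate_mean: float
    spike_times: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.trial_index < 0:
            raise ValidationError("trial_index must be >= 0")
        if not (self.rate_mean >= 0):
            raise ValidationError(f"rate_mean must be >= 0, got {self.rate_mean}")
        if self.spike_times is not None:
            st = tuple(float(t) for t in self.spike_times)
            object.__setattr__(self, "spike_times", st)
            T = self.condition.duration
            if any(t < -1e-9 or t > T + 1e-9 for t in st):
                raise ValidationError("spike times must lie within [0, duration]")
            if abs(self.rate_mean - len(st) / T) > 1e-9:
                raise ValidationError("rate_mean inconsistent with spike count/duration")


@dataclass
class UnitRecord:
    """All trials of one single unit, with its animal/hemisphere/group labels."""

    unit_id: str
    animal_id: str
    hemisphere: str
    group: str
    trials: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValidationError(f"unknown hemisphere {self.hemisphere!r}")
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")

    def batteries(self) -> tuple:
        return tuple(sorted({t.condition.battery for t in self.trials}))

    def trials_for_battery(self, battery: str):
        return [t for t in self.trials if t.condition.battery == battery]

    def blank_trials(self, battery: Optional[str] = None):
        return [
            t
            for t in self.trials
            if t.condition.is_blank and (battery is None or t.condition.battery == battery)
        ]

    def blank_rate(self, battery: Optional[str] = None) -> float:
        blanks = self.blank_trials(battery)
        if not blanks:
            where = f"battery {battery}" if battery else "record"
            raise ValidationError(f"unit {self.unit_id}: no blank trials in {where}")
        return float(np.mean([t.rate_mean for t in blanks]))


@dataclass
class TuningCurve:
    """Blank-subtracted mean +/- SE responses over one varied stimulus parameter.

    Responses may be negative: suppression below the background rate is a real
    feature of these data and is preserved here; downstream indices decide how
    to rectify.
    """

    varied_parameter: str
    x_values: np.ndarray
    responses: np.ndarray
    response_se: np.ndarray
    response_modality: str = "mean"  # "mean" | "F1"
    blank_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.varied_parameter not in CURVE_PARAMETERS:
            raise ValidationError(f"unknown varied_parameter {self.varied_parameter!r}")
        if self.response_modality not in ("mean", "F1"):
            raise ValidationError(f"unknown response_modality {self.response_modality!r}")
        self.x_values = np.asarray(self.x_values, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        self.response_se = np.asarray(self.response_se, dtype=float)
        if not (len(self.x_values) == len(self.responses) == len(self.response_se)):
            raise ValidationError("x_values, responses, response_se must have equal length")
        if np.any(self.response_se < 0):
            raise ValidationError("response_se must be >= 0")
        if not (self.blank_rate >= 0):
            raise ValidationError("blank_rate must be >= 0")
        if self.varied_parameter in ("spatial_frequency", "temporal_frequency", "contrast"):
            if np.any(np.diff(self.x_values) <= 0):
                raise ValidationError(
                    f"x_values must be strictly increasing for {self.varied_parameter} curves"
                )

    def __len__(self) -> int:
        return len(self.x_values)
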