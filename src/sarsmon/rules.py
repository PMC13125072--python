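"""Sensor-agent threshold rule engine.

Each sensor agent derives a High / Low / Normal status for its vital from
fixed cutoffs and announces non-Normal findings to the rest of the system as
*Tell* messages (an agent's outbound assertion of a derived condition, e.g.
``Tell[Has_Fever(P, High)]``). The rule set covers room temperature, blood
oxygen saturation, body temperature, heart rate, blood sugar, ECG, blood
pressure and an unconditional fire-level relay.

Boundary conventions: a vital is High when value >= high cutoff, Low when
value <= low cutoff, Normal strictly in between; the inclusive extreme rules
win over Normal at the cutoffs, so the three statuses partition the real
line. Blood pressure is a compound vital: High fires when either component
reaches its high cutoff, Low when either component falls to its low cutoff,
and High takes precedence when both fire.

Two threshold profiles ship with the package. ``paper_faithful`` encodes the
rule table exactly as printed — including flagging blood oxygen saturation
*high* at >= 90 and the 0.6–1.2 ECG scale. ``clinical`` flags SpO2 <= 90 as
Low (desaturation), uses the cohort's 80–120 ECG index scale and a 38 degC
fever cutoff, and is the profile the multi-agent simulation uses by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "VitalThreshold",
    "BloodPressureThreshold",
    "ThresholdConfig",
    "VitalStatus",
    "TellMessage",
    "evaluate_record",
    "evaluate_fire",
    "load_profile",
]

HIGH, LOW, NORMAL = "High", "Low", "Normal"
FIRE_LEVELS = ("High", "Low", "No_Risk")


@dataclass(frozen=True)
class VitalThreshold:
    """Cutoffs and rule metadata for one single-channel vital."""

    vital: str
    units: str
    high: float | None = None
    low: float | None = None
    high_rule: str | None = None
    low_rule: str | None = None
    normal_rule: str | None = None
    high_predicate: str | None = None
    low_predicate: str | None = None
    tell_high: bool = False
    tell_low: bool = False
    #: printed argument of the low-side Tell (hypothermia is told as 'High',
    #: meaning a high degree of hypothermia)
    low_message_level: str = LOW

    def __post_init__(self):
        if self.high is not None and self.low is not None and self.low >= self.high:
            raise ValueError(
                f"{self.vital}: low cutoff {self.low} must be below high {self.high}"
            )


@dataclass(frozen=True)
class BloodPressureThreshold:
    """Compound systolic/diastolic cutoffs (printed as e.g. 'BP >= 145/100')."""

    high_systolic: float = 145.0
    high_diastolic: float = 100.0
    low_systolic: float = 100.0
    low_diastolic: float = 60.0
    high_rule: str = "R24"
    low_rule: str = "R26"
    normal_rule: str = "R27"
    high_predicate: str = "High_Blood_Pressure"
    low_predicate: str = "Low_Blood_Pressure"
    tell_high: bool = True
    tell_low: bool = False


@dataclass(frozen=True)
class ThresholdConfig:
    """A named profile of per-vital thresholds plus the compound BP rule."""

    name: str
    vitals: dict[str, VitalThreshold]
    blood_pressure: BloodPressureThreshold = field(
        default_factory=BloodPressureThreshold
    )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "vitals": {k: asdict(v) for k, v in self.vitals.items()},
            "blood_pressure": asdict(self.blood_pressure),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdConfig":
        return cls(
            name=d["name"],
            vitals={k: VitalThreshold(**v) for k, v in d["vitals"].items()},
            blood_pressure=BloodPressureThreshold(**d.get("blood_pressure", {})),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ThresholdConfig":
        return cls.from_dict(yaml.safe_load(text))


def load_profile(name: str = "paper_faithful") -> ThresholdConfig:
    """Load a shipped threshold profile (``paper_faithful`` or ``clinical``)."""
    ref = resources.files("sarsmon") / "profiles" / f"{name}.yaml"
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise ValueError(f"unknown threshold profile {name!r}") from None
    return ThresholdConfig.from_yaml(text)


@dataclass(frozen=True)
class VitalStatus:
    """Derived level for one vital with the rule that fired."""

    vital: str
    level: str
    source_rule: str | None
    value: float | None = None


@dataclass(frozen=True)
class TellMessage:
    """Outbound assertion of a derived non-Normal condition."""

    predicate: str
    patient_id: object
    level: str
    tick: int
    rule: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _f_to_c(temp_f: float) -> float:
    return (temp_f - 32.0) * 5.0 / 9.0


def _record_value(record, key):
    v = record.get(key) if hasattr(record, "get") else getattr(record, key, None)
    if v is None:
        return None
    v = float(v)
    return None if np.isnan(v) else v


def evaluate_record(
    record, thresholds: ThresholdConfig
) -> tuple[list[VitalStatus], list[TellMessage]]:
    """Derive one status per configured vital and the resulting Tell messages.

    ``record`` may be a :class:`~sarsmon.cohort.VitalRecord`, a mapping or a
    DataFrame row; missing vitals are skipped. Body temperature is accepted
    as ``body_temp_f`` (degF, converted) or ``body_temp_c``; all comparisons
    run in the profile's units (degC for temperature).
    """
    patient_id = _record_value_raw(record, "patient_id")
    tick = int(_record_value(record, "tick") or 0)
    statuses: list[VitalStatus] = []
    tells: list[TellMessage] = []

    for vital, th in thresholds.vitals.items():
        if vital == "body_temp_c":
            value = _record_value(record, "body_temp_c")
            if value is None:
                f = _record_value(record, "body_temp_f")
                value = _f_to_c(f) if f is not None else None
        else:
            value = _record_value(record, vital)
        if value is None:
            continue
        if th.high is not None and value >= th.high:
            statuses.append(VitalStatus(vital, HIGH, th.high_rule, value))
            if th.tell_high:
                tells.append(
                    TellMessage(th.high_predicate, patient_id, HIGH, tick, th.high_rule)
                )
        elif th.low is not None and value <= th.low:
            statuses.append(VitalStatus(vital, LOW, th.low_rule, value))
            if th.tell_low:
                tells.append(
                    TellMessage(
                        th.low_predicate,
                        patient_id,
                        th.low_message_level,
                        tick,
                        th.low_rule,
                    )
                )
        else:
            statuses.append(VitalStatus(vital, NORMAL, th.normal_rule, value))

    bp = thresholds.blood_pressure
    sys_v = _record_value(record, "systolic_bp")
    dia_v = _record_value(record, "diastolic_bp")
    if sys_v is not None and dia_v is not None:
        high_fires = sys_v >= bp.high_systolic or dia_v >= bp.high_diastolic
        low_fires = sys_v <= bp.low_systolic or dia_v <= bp.low_diastolic
        if high_fires:  # High precedence when both components fire
            statuses.append(VitalStatus("blood_pressure", HIGH, bp.high_rule))
            if bp.tell_high:
                tells.append(
                    TellMessage(bp.high_predicate, patient_id, HIGH, tick, bp.high_rule)
                )
        elif low_fires:
            statuses.append(VitalStatus("blood_pressure", LOW, bp.low_rule))
            if bp.tell_low:
                tells.append(
                    TellMessage(bp.low_predicate, patient_id, LOW, tick, bp.low_rule)
                )
        else:
            statuses.append(VitalStatus("blood_pressure", NORMAL, bp.normal_rule))

    return statuses, tells


def _record_value_raw(record, key):
    return record.get(key) if hasattr(record, "get") else getattr(record, key, None)


def evaluate_fire(level: str, patient_id=None, tick: int = 0) -> TellMessage:
    """Relay the current fire level unconditionally (the fire sensor rule)."""
    if level not in FIRE_LEVELS:
        raise ValueError(f"invalid fire level {level!r}; expected one of {FIRE_LEVELS}")
    return TellMessage("Current_Fire_Level", patient_id, level, tick, "R28")
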