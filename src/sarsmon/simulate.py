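"""Tick-based multi-agent monitoring and escalation simulation.

Patients, doctors and seven stationary sensor agents (blood oxygen,
environmental, body temperature, heart rate, ECG, blood pressure, room
temperature) populate a bounded grid. Each tick: mobile agents wander one
unit with reflecting boundaries; every patient's risk probability is updated
from the sensor-derived rule statuses of their current vital-sign record (a
logistic squash of a weighted non-Normal status count) plus Gaussian drift,
then clipped to [0, 1]; critical conditions are checked and escalated —
the nearest doctor is notified at the critical level, an alert is generated
at the extremely-critical level, and an ambulance is called at the
life-threatening level; finally the population average probability is
recomputed.

Randomness is split into independent named streams (setup, movement, drift)
derived from one master seed, so the event log is a pure function of
(config, seed, number of ticks).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import CHANNELS, CohortConfig, generate_cohort
from .rules import NORMAL, ThresholdConfig, load_profile, evaluate_record

__all__ = ["SimConfig", "AgentState", "EscalationEvent", "WorldState",
           "setup", "step", "run", "call_doctor", "average_probability"]

SENSOR_KINDS = (
    "sensor:blood_oxygen",
    "sensor:environmental",
    "sensor:body_temperature",
    "sensor:heart_rate",
    "sensor:ecg",
    "sensor:blood_pressure",
    "sensor:room_temperature",
)

SEVERITY_ACTIONS = {
    "critical": "doctor_notified",
    "extremely_critical": "alert_generated",
    "life_threatening": "ambulance_called",
}


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters: population, grid, dynamics and escalation."""

    n_patients: int = 20
    n_doctors: int = 2
    grid_size: int = 33
    #: escalation cutoffs on the patient risk probability
    critical: float = 0.6
    extremely_critical: float = 0.8
    life_threatening: float = 0.95
    #: probability-update weights: base intercept and per non-Normal status
    status_weight: float = 1.2
    intercept: float = -3.0
    drift_sd: float = 0.05
    threshold_profile: str = "clinical"
    #: cohort supplying each patient's per-tick vital records
    cohort: CohortConfig | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 0 or self.n_doctors < 0:
            raise ValueError("agent counts must be non-negative")
        if self.grid_size <= 0:
            raise ValueError("grid size must be positive")
        if not 0 < self.critical <= self.extremely_critical <= self.life_threatening <= 1:
            raise ValueError("escalation cutoffs must be increasing within (0, 1]")


@dataclass
class AgentState:
    agent_id: int
    kind: str  # 'patient', 'doctor' or 'sensor:<channel>'
    x: float
    y: float
    probability: float | None = None  # patients only
    is_doctor: bool = False
    severity: str | None = None  # colour tag: None/'critical'/...
    attributes: dict = field(default_factory=dict)

    @property
    def mobile(self) -> bool:
        return self.kind in ("patient", "doctor")


@dataclass(frozen=True)
class EscalationEvent:
    tick: int
    patient_id: int
    severity: str
    action: str
    responder_id: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class WorldState:
    agents: list[AgentState]
    tick: int
    event_log: list[EscalationEvent]
    config: SimConfig
    thresholds: ThresholdConfig
    average_probability_: float | None = None
    _records: dict | None = None
    _move_rng: np.random.Generator | None = None
    _drift_rng: np.random.Generator | None = None

    def patients(self) -> list[AgentState]:
        return [a for a in self.agents if a.kind == "patient"]

    def doctors(self) -> list[AgentState]:
        return [a for a in self.agents if a.kind == "doctor"]


def setup(config: SimConfig | None = None, seed: int | None = None) -> WorldState:
    """Create the initial world: agents placed, tick 0, empty event log."""
    import warnings

    if config is None:
        config = SimConfig()
    if seed is not None:
        config = SimConfig(**{**asdict_config(config), "seed": seed})
    if config.n_doctors == 0 and config.n_patients > 0:
        warnings.warn(
            "no doctor agents: critical escalations fall back to alerts",
            stacklevel=2,
        )
    master = np.random.SeedSequence(config.seed)
    ss_setup, ss_move, ss_drift, ss_cohort = master.spawn(4)
    rng = np.random.default_rng(ss_setup)

    agents: list[AgentState] = []
    next_id = 0
    for _ in range(config.n_patients):
        x, y = rng.uniform(0, config.grid_size, size=2)
        agents.append(
            AgentState(next_id, "patient", x, y, probability=float(rng.uniform(0, 0.3)))
        )
        next_id += 1
    for _ in range(config.n_doctors):
        x, y = rng.uniform(0, config.grid_size, size=2)
        agents.append(AgentState(next_id, "doctor", x, y, is_doctor=True))
        next_id += 1
    for kind in SENSOR_KINDS:
        x, y = rng.uniform(0, config.grid_size, size=2)
        agents.append(AgentState(next_id, kind, x, y))
        next_id += 1

    cohort_cfg = config.cohort
    if cohort_cfg is None:
        cohort_cfg = CohortConfig(
            n_patients=max(config.n_patients, 1),
            records_per_patient=512,
            missing_rate=0.0,
            seed=int(ss_cohort.generate_state(1)[0] % (2**31)),
        )
    records = None
    if config.n_patients > 0:
        df = generate_cohort(cohort_cfg)
        # index vitals by (patient, tick) once for O(1) per-tick lookup
        records = {
            "frame": df,
            "by_patient": {
                pid: sub.set_index("tick")[list(CHANNELS)]
                for pid, sub in df.groupby("patient_id")
            },
            "n_ticks": int(df["tick"].max()) + 1,
        }

    return WorldState(
        agents=agents,
        tick=0,
        event_log=[],
        config=config,
        thresholds=load_profile(config.threshold_profile),
        _records=records,
        _move_rng=np.random.default_rng(ss_move),
        _drift_rng=np.random.default_rng(ss_drift),
    )


def asdict_config(config: SimConfig) -> dict:
    d = asdict(config)
    if d.get("cohort") is not None:
        d["cohort"] = config.cohort
    return d


def _wander(agent: AgentState, grid: int, rng: np.random.Generator) -> None:
    angle = rng.uniform(0.0, 2.0 * math.pi)
    nx = agent.x + math.cos(angle)
    ny = agent.y + math.sin(angle)
    # reflecting boundaries
    if nx < 0:
        nx = -nx
    elif nx > grid:
        nx = 2 * grid - nx
    if ny < 0:
        ny = -ny
    elif ny > grid:
        ny = 2 * grid - ny
    agent.x, agent.y = nx, ny


def _patient_record(world: WorldState, patient_index: int) -> dict:
    tables = world._records["by_patient"]
    pid = patient_index % len(tables)
    tick = world.tick % world._records["n_ticks"]
    row = tables[pid].loc[tick]
    rec = {k: row[k] for k in CHANNELS}
    rec.update(patient_id=pid, tick=tick)
    return rec


def step(world: WorldState) -> WorldState:
    """Advance the simulation by exactly one tick (mutates and returns world)."""
    cfg = world.config
    # 1. movement
    for agent in world.agents:
        if agent.mobile:
            _wander(agent, cfg.grid_size, world._move_rng)
    # 2. probability updates from sensor statuses + drift, clipped
    for idx, patient in enumerate(world.patients()):
        record = _patient_record(world, idx)
        statuses, _ = evaluate_record(record, world.thresholds)
        n_abnormal = sum(1 for s in statuses if s.level != NORMAL)
        target = 1.0 / (
            1.0 + math.exp(-(cfg.intercept + cfg.status_weight * n_abnormal))
        )
        drift = float(world._drift_rng.normal(0.0, cfg.drift_sd))
        patient.probability = min(1.0, max(0.0, target + drift))
    # 3. critical-condition check and escalation (one event per patient/tick,
    #    at the highest severity reached)
    for patient in world.patients():
        p = patient.probability
        if p >= cfg.life_threatening:
            severity = "life_threatening"
        elif p >= cfg.extremely_critical:
            severity = "extremely_critical"
        elif p >= cfg.critical:
            severity = "critical"
        else:
            patient.severity = None
            continue
        patient.severity = severity
        if severity == "critical":
            world.event_log.append(call_doctor(world, patient.agent_id))
        else:
            world.event_log.append(
                EscalationEvent(
                    tick=world.tick,
                    patient_id=patient.agent_id,
                    severity=severity,
                    action=SEVERITY_ACTIONS[severity],
                )
            )
    # 4. time advancement and population statistic
    world.tick += 1
    world.average_probability_ = average_probability(world)
    return world


def call_doctor(world: WorldState, patient_id: int) -> EscalationEvent:
    """Notify the doctor nearest to the patient (ties: lowest agent id).

    Without any doctor agent the escalation degrades to a generated alert.
    """
    import warnings

    patient = next(a for a in world.agents if a.agent_id == patient_id)
    doctors = world.doctors()
    if not doctors:
        warnings.warn("no doctors available; generating alert instead", stacklevel=2)
        return EscalationEvent(
            tick=world.tick,
            patient_id=patient_id,
            severity="critical",
            action="alert_generated",
        )
    nearest = min(
        doctors,
        key=lambda d: (math.hypot(d.x - patient.x, d.y - patient.y), d.agent_id),
    )
    return EscalationEvent(
        tick=world.tick,
        patient_id=patient_id,
        severity="critical",
        action="doctor_notified",
        responder_id=nearest.agent_id,
    )


def average_probability(world: WorldState) -> float | None:
    """Mean probability over probability-bearing agents; None when empty."""
    probs = [a.probability for a in world.agents if a.probability is not None]
    if not probs:
        return None
    return float(sum(probs) / len(probs))


def run(
    config: SimConfig | None = None,
    n_ticks: int = 100,
    seed: int | None = None,
    events_path=None,
) -> WorldState:
    """Set up and advance ``n_ticks`` ticks; optionally write a JSON-lines
    event log."""
    world = setup(config, seed=seed)
    for _ in range(n_ticks):
        step(world)
    if events_path is not None:
        with open(events_path, "w") as fh:
            for ev in world.event_log:
                fh.write(json.dumps(ev.to_dict()) + "\n")
    return world
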