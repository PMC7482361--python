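"""Tendon mechanics from staged isometric plantarflexion load cases.

Measurements are taken at rest and at three submaximal isometric torque
levels (25, 50 and 70% of maximal voluntary contraction, MVC).  For each
condition:

* net torque  = torque under load - torque at rest (Nm)
* force       = net torque / moment arm (moment arm in cm -> m)   [N]
* elongation  = tendon length under load - resting length         [mm]
* strain      = elongation / resting length (stored as fraction)
* stress      = force / loaded CSA ("true" stress, MPa = N/mm^2)

Mechanical stiffness (N/mm) is the ordinary-least-squares slope of force vs
elongation over the three loaded conditions; Young's modulus (GPa) the slope
of stress vs strain over the same three points, divided by 1000 (MPa ->
GPa).  The rest point is deliberately excluded from both fits: including
(0, 0) would contaminate the linear-region slope with toe-region behaviour.
Length-normalised stiffness (kN/strain) is stiffness x resting length /
1000.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LoadCase",
    "MechanicsSummary",
    "SubjectRecord",
    "tendon_force",
    "build_load_cases",
    "stiffness_and_modulus",
    "LOAD_LEVELS",
]

LOAD_LEVELS = (25, 50, 70)  # %MVC loaded conditions

Level = Literal["rest", 25, 50, 70]


def tendon_force(net_torque: float, moment_arm: float) -> float:
    """Tendon force (N) from net ankle torque (Nm) and moment arm (cm)."""
    if moment_arm <= 0:
        raise ValueError(f"moment arm must be positive, got {moment_arm} cm")
    return net_torque / (moment_arm / 100.0)


@dataclass(frozen=True)
class LoadCase:
    """A single loading condition with all derived per-condition quantities."""

    level: Level
    torque_load: float  # Nm
    torque_rest: float  # Nm
    net_torque: float  # Nm
    length: float  # mm
    csa_load: float  # mm^2
    force: float  # N
    elongation: float  # mm
    stress: float  # MPa
    strain: float  # fraction

    def __post_init__(self) -> None:
        if abs(self.net_torque - (self.torque_load - self.torque_rest)) > 1e-9:
            raise ValueError("net_torque must equal torque_load - torque_rest")
        if self.csa_load <= 0:
            raise ValueError("loaded CSA must be positive")

    @property
    def strain_percent(self) -> float:
        return 100.0 * self.strain


@dataclass(frozen=True)
class MechanicsSummary:
    """Stiffness, modulus and length-normalised stiffness for one subject."""

    stiffness: float  # N/mm
    youngs_modulus: float  # GPa
    normalized_stiffness: float  # kN/strain
    r_squared_force: float
    r_squared_stress: float
    resting_length: float  # mm

    def __post_init__(self) -> None:
        expected = self.stiffness * self.resting_length / 1000.0
        if abs(self.normalized_stiffness - expected) > 1e-9 * max(1.0, abs(expected)):
            raise ValueError(
                "normalized_stiffness must equal stiffness * resting_length / 1000"
            )
        for r2 in (self.r_squared_force, self.r_squared_stress):
            if not (0.0 <= r2 <= 1.0 + 1e-12):
                raise ValueError(f"r^2 out of [0, 1]: {r2}")

    def to_dict(self) -> dict:
        return {
            "stiffness_N_per_mm": self.stiffness,
            "youngs_modulus_GPa": self.youngs_modulus,
            "normalized_stiffness_kN_per_strain": self.normalized_stiffness,
            "r_squared_force_elongation": self.r_squared_force,
            "r_squared_stress_strain": self.r_squared_stress,
            "resting_length_mm": self.resting_length,
        }


@dataclass
class SubjectRecord:
    """Per-subject mechanics inputs: moment arm, MVC torque and raw per-level
    measurements (possibly several trials per level)."""

    subject_id: str
    group: Literal["runner", "control"]
    moment_arm: float  # cm
    mvc_torque: float  # Nm
    measurements: pd.DataFrame = field(repr=False)
    # columns: level, torque_load_Nm, torque_rest_Nm, length_mm, csa_mm2

    def __post_init__(self) -> None:
        required = {"level", "torque_load_Nm", "torque_rest_Nm", "length_mm", "csa_mm2"}
        missing = required - set(self.measurements.columns)
        if missing:
            raise ValueError(f"subject {self.subject_id}: missing columns {missing}")


def _require_rest(df: pd.DataFrame, subject: str) -> pd.Series:
    rest = df[df["level"].astype(str) == "rest"]
    if rest.empty:
        raise ValueError(f"subject {subject}: missing rest case")
    return rest[["torque_load_Nm", "torque_rest_Nm", "length_mm", "csa_mm2"]].mean()


def build_load_cases(
    record: SubjectRecord, mode: Literal["mean", "per_trial"] = "mean"
) -> list[LoadCase]:
    """Turn raw per-level measurements into fully derived load cases.

    Replicate trials at the same level are averaged before derivation
    (``mode='mean'``, the default) or kept as individual cases
    (``mode='per_trial'``).  The resting 3DUS length is the strain/elongation
    reference; the rest case itself is emitted with zero force and strain.
    """
    df = record.measurements
    rest = _require_rest(df, record.subject_id)
    resting_length = float(rest["length_mm"])

    def derive(level: Level, row: Mapping[str, float]) -> LoadCase:
        net = float(row["torque_load_Nm"]) - float(row["torque_rest_Nm"])
        force = tendon_force(net, record.moment_arm)
        elong = float(row["length_mm"]) - resting_length
        return LoadCase(
            level=level,
            torque_load=float(row["torque_load_Nm"]),
            torque_rest=float(row["torque_rest_Nm"]),
            net_torque=net,
            length=float(row["length_mm"]),
            csa_load=float(row["csa_mm2"]),
            force=force,
            elongation=elong,
            stress=force / float(row["csa_mm2"]),
            strain=elong / resting_length,
        )

    cases = [derive("rest", rest)]
    for level in LOAD_LEVELS:
        sub = df[df["level"].astype(str) == str(level)]
        if sub.empty:
            continue
        if mode == "mean":
            cases.append(derive(level, sub.mean(numeric_only=True)))
        else:
            cases.extend(derive(level, row) for _, row in sub.iterrows())
    return cases


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and r^2 of an ordinary least-squares line."""
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), min(max(r2, 0.0), 1.0)


def stiffness_and_modulus(cases: Iterable[LoadCase]) -> MechanicsSummary:
    """Stiffness, Young's modulus and length-normalised stiffness from the
    three loaded conditions (order-independent; a rest case may be present
    and is ignored by the fits)."""
    loaded = [c for c in cases if c.level != "rest"]
    levels = sorted(c.level for c in loaded)
    if levels != sorted(LOAD_LEVELS):
        raise ValueError(
            f"need exactly the {LOAD_LEVELS} %MVC cases, got levels {levels}"
        )
    loaded.sort(key=lambda c: c.level)
    elong = np.array([c.elongation for c in loaded])
    force = np.array([c.force for c in loaded])
    strain = np.array([c.strain for c in loaded])
    stress = np.array([c.stress for c in loaded])
    if np.ptp(elong) < 1e-12:
        raise ValueError("coincident elongations: stiffness slope undefined")
    resting_length = float(loaded[0].length - loaded[0].elongation)

    stiffness, r2_force = _ols(elong, force)
    modulus_mpa, r2_stress = _ols(strain, stress)
    return MechanicsSummary(
        stiffness=stiffness,
        youngs_modulus=modulus_mpa / 1000.0,
        normalized_stiffness=stiffness * resting_length / 1000.0,
        r_squared_force=r2_force,
        r_squared_stress=r2_stress,
        resting_length=resting_length,
    )
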