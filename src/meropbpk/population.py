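"""Virtual individuals and populations with between-subject variability.

Demographics (weight, height, age) are sampled around the reference adult;
eGFR is uniform within the assigned CKD stage interval; multiplicative
log-normal variability (default CV 30%) acts on the transporter and DPEP1
Vmax values and on the distribution volume.  All sampling is reproducible
under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ckd_scaling import STAGE_EGFR_RANGES, CKDStage, apply_ckd
from .config import load_yaml, packaged_config
from .drug_physiology import (
    EGFR_NORMAL,
    PhysiologyParameters,
    ValidationError,
    physiology_from_config,
)


class SpecError(ValueError):
    """Impossible population specification."""


@dataclass(frozen=True)
class VirtualIndividual:
    """One virtual subject: demographics, physiology and scaled activities."""

    age: float  # years
    height: float  # cm
    weight: float  # kg
    sex: str
    physiology: PhysiologyParameters
    activity_multipliers: dict  # disease/inhibition scaling per process, in [0, 1]
    vmax_multipliers: dict  # log-normal between-subject variability per process
    volume_multiplier: float  # variability on distribution volume
    egfr: float  # mL/min/1.73 m²
    stage: int | None = None  # None = healthy

    def scaled_processes(self, processes):
        """Processes with this subject's variability and disease scaling applied."""
        out = []
        for p in processes:
            out.append(
                replace(
                    p,
                    vmax=p.vmax * self.vmax_multipliers.get(p.name, 1.0),
                    activity_multiplier=p.activity_multiplier
                    * self.activity_multipliers.get(p.name, 1.0),
                )
            )
        return out


@dataclass(frozen=True)
class PopulationSpec:
    """Sampling specification for a virtual population."""

    n: int
    stage: int | str | None = None  # None or 'healthy', else 3/4/5
    seed: int = 0
    weight_mean: float = 73.0
    weight_cv: float = 0.15
    height_mean: float = 176.0
    height_sd: float = 7.0
    age_range: tuple = (20.0, 70.0)
    vmax_cv: float = 0.30
    volume_cv: float = 0.30
    healthy_egfr_cv: float = 0.12

    def __post_init__(self):
        if self.n < 1:
            raise SpecError("n must be >= 1")
        for cv in (self.weight_cv, self.vmax_cv, self.volume_cv, self.healthy_egfr_cv):
            if cv < 0:
                raise SpecError("CVs must be non-negative")
        st = self.stage
        if st not in (None, "healthy", 3, 4, 5):
            raise SpecError(f"stage must be healthy/3/4/5, got {st!r}")

    @property
    def is_healthy(self) -> bool:
        return self.stage in (None, "healthy")


def _lognormal(rng: np.random.Generator, cv: float, size=None):
    if cv == 0:
        return np.ones(size) if size else 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    # mean-preserving multiplicative noise
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def generate_population(spec: PopulationSpec) -> list:
    """Sample ``spec.n`` virtual individuals, reproducibly under the seed."""
    rng = np.random.default_rng(spec.seed)
    ref = load_yaml(packaged_config("physiology_reference.yaml"))
    out = []
    for _ in range(spec.n):
        weight = spec.weight_mean * _lognormal(rng, spec.weight_cv)
        height = max(rng.normal(spec.height_mean, spec.height_sd), 120.0)
        age = rng.uniform(*spec.age_range)
        phys = physiology_from_config(ref, weight=weight, height=height)
        vmax_mult = {name: float(_lognormal(rng, spec.vmax_cv)) for name in ("OAT3", "NPT1", "DPEP1")}
        vol_mult = float(_lognormal(rng, spec.volume_cv))
        if spec.is_healthy:
            egfr = EGFR_NORMAL * float(_lognormal(rng, spec.healthy_egfr_cv))
            phys = replace(phys, gfr=egfr * phys.body_surface_area / 1.73)
            ind = VirtualIndividual(
                age=age, height=height, weight=weight, sex="male",
                physiology=phys,
                activity_multipliers={"OAT3": 1.0, "NPT1": 1.0, "DPEP1": 1.0},
                vmax_multipliers=vmax_mult,
                volume_multiplier=vol_mult,
                egfr=egfr,
            )
        else:
            lo, hi = STAGE_EGFR_RANGES[int(spec.stage)]
            egfr = float(rng.uniform(lo, hi))
            healthy = VirtualIndividual(
                age=age, height=height, weight=weight, sex="male",
                physiology=phys,
                activity_multipliers={"OAT3": 1.0, "NPT1": 1.0, "DPEP1": 1.0},
                vmax_multipliers=vmax_mult,
                volume_multiplier=vol_mult,
                egfr=phys.egfr,
            )
            ind = apply_ckd(healthy, egfr, CKDStage(int(spec.stage)))
        out.append(ind)
    return out


def archetype(stage: int | str | None = None, egfr: float | None = None) -> VirtualIndividual:
    """The deterministic stage archetype (all variability off).

    For CKD stages the eGFR defaults to the stage-interval midpoint.
    """
    phys = physiology_from_config(load_yaml(packaged_config("physiology_reference.yaml")))
    healthy = VirtualIndividual(
        age=30.0, height=phys.height, weight=phys.body_weight, sex="male",
        physiology=phys,
        activity_multipliers={"OAT3": 1.0, "NPT1": 1.0, "DPEP1": 1.0},
        vmax_multipliers={"OAT3": 1.0, "NPT1": 1.0, "DPEP1": 1.0},
        volume_multiplier=1.0,
        egfr=phys.egfr,
    )
    if stage in (None, "healthy"):
        return healthy
    lo, hi = STAGE_EGFR_RANGES[int(stage)]
    target = 0.5 * (lo + hi) if egfr is None else egfr
    return apply_ckd(healthy, target, CKDStage(int(stage)))


def build_individual_model(individual: VirtualIndividual, drug, processes):
    """PBPK model for one subject (variability and disease scaling applied).

    The between-subject volume multiplier acts on the distribution volumes
    (organs and plasma), not on the mechanistic kidney sub-volumes.
    """
    from .pbpk_core import build_model  # local import avoids a cycle

    phys = individual.physiology
    vm = individual.volume_multiplier
    if vm != 1.0:
        volumes = {k: v * vm for k, v in phys.organ_volumes.items() if k != "kidney"}
        volumes["kidney"] = phys.organ_volumes["kidney"]
        phys = replace(
            phys,
            organ_volumes=volumes,
            venous_plasma_volume=phys.venous_plasma_volume * vm,
            arterial_plasma_volume=phys.arterial_plasma_volume * vm,
        )
    return build_model(drug, individual.scaled_processes(processes), phys)


def population_frame(individuals) -> pd.DataFrame:
    """One row per individual with all sampled parameters (CSV dump)."""
    rows = []
    for i, ind in enumerate(individuals):
        rows.append(
            {
                "id": i,
                "age_y": ind.age,
                "height_cm": ind.height,
                "weight_kg": ind.weight,
                "sex": ind.sex,
                "egfr_ml_min_1_73": ind.egfr,
                "gfr_ml_min": ind.physiology.gfr,
                "stage": ind.stage if ind.stage is not None else "healthy",
                "oat3_activity": ind.activity_multipliers.get("OAT3", 1.0),
                "npt1_activity": ind.activity_multipliers.get("NPT1", 1.0),
                "dpep1_activity": ind.activity_multipliers.get("DPEP1", 1.0),
                "oat3_vmax_mult": ind.vmax_multipliers.get("OAT3", 1.0),
                "npt1_vmax_mult": ind.vmax_multipliers.get("NPT1", 1.0),
                "dpep1_vmax_mult": ind.vmax_multipliers.get("DPEP1", 1.0),
                "volume_mult": ind.volume_multiplier,
            }
        )
    return pd.DataFrame(rows)
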