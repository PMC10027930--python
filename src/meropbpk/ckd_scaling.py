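"""Scaling of a healthy individual to chronic kidney disease stages 3-5.

Renal secretory transport (OAT3, NPT1) is reduced proportionally to the
impaired filtration per the intact nephron hypothesis: the scaling factor
is eGFR_CKD / eGFR_normal with eGFR_normal = 106.78 mL/min/1.73 m².
Renal DPEP1 expression is reduced to 69% (stage 3) or 64% (stages 4-5) of
the healthy level.  A minimal pathophysiology delta set shrinks kidney
volume and renal plasma flow with the same eGFR ratio (the freed flow is
redistributed to the rest compartment so cardiac output is conserved).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .drug_physiology import EGFR_NORMAL, PhysiologyParameters, ValidationError

STAGE_EGFR_RANGES = {3: (31.0, 60.0), 4: (16.0, 30.0), 5: (1.0, 15.0)}
DPEP1_FACTORS = {3: 0.69, 4: 0.64, 5: 0.64}

#: interdialytic fluid overload of end-stage renal disease (L of excess
#: extracellular water); typical interdialytic weight gain is 2-4 kg
STAGE5_EXCESS_ECW = 4.0


class DomainError(ValueError):
    """Argument outside its physiological domain."""


@dataclass(frozen=True)
class CKDStage:
    """A chronic-kidney-disease stage and its eGFR interval (mL/min/1.73 m²)."""

    stage: int

    def __post_init__(self):
        if self.stage not in STAGE_EGFR_RANGES:
            raise DomainError(f"CKD stage must be 3, 4 or 5, got {self.stage}")

    @property
    def egfr_range(self) -> tuple[float, float]:
        return STAGE_EGFR_RANGES[self.stage]

    def contains(self, egfr: float) -> bool:
        lo, hi = self.egfr_range
        return lo <= egfr <= hi


@dataclass(frozen=True)
class ScalingResult:
    transporter_scaling_factor: float  # eGFR_CKD / eGFR_normal
    dpep1_scaling_factor: float
    gfr_ml_min: float  # absolute GFR after BSA conversion


def transporter_scaling_factor(egfr_ckd: float) -> float:
    """Intact-nephron-hypothesis factor eGFR_CKD / eGFR_normal.

    Applied identically to the OAT3 and NPT1 activity multipliers.
    """
    if not egfr_ckd > 0:
        raise DomainError(f"eGFR must be positive, got {egfr_ckd}")
    return egfr_ckd / EGFR_NORMAL


def dpep1_scaling_factor(stage: CKDStage | int) -> float:
    """Residual renal DPEP1 expression by stage (0.69 / 0.64 / 0.64)."""
    s = stage.stage if isinstance(stage, CKDStage) else stage
    if s not in DPEP1_FACTORS:
        raise DomainError(f"CKD stage must be 3, 4 or 5, got {s}")
    return DPEP1_FACTORS[s]


def scale_physiology(physiology: PhysiologyParameters, egfr_ckd: float,
                     excess_ecw: float = 0.0) -> PhysiologyParameters:
    """Apply the CKD pathophysiology deltas to a healthy physiology.

    GFR is set from eGFR x BSA / 1.73; kidney sub-volumes and renal plasma
    flow shrink with the eGFR ratio (floored at 5% to keep the vascular
    space non-degenerate), and the flow difference is rerouted to the rest
    compartment so the flow-conservation invariant holds.  ``excess_ecw``
    adds fluid-overload extracellular water (end-stage disease).
    """
    ratio = transporter_scaling_factor(egfr_ckd)
    shrink = max(ratio, 0.05)
    gfr = egfr_ckd * physiology.body_surface_area / 1.73
    flows = dict(physiology.organ_flows)
    q_kid = flows["kidney"] * shrink
    flows["rest"] = flows["rest"] + (flows["kidney"] - q_kid)
    flows["kidney"] = q_kid
    volumes = dict(physiology.organ_volumes)
    kp = physiology.kidney_plasma_volume * shrink
    kc = physiology.kidney_cell_volume * shrink
    kl = physiology.kidney_lumen_volume * shrink
    volumes["kidney"] = kp + kc + kl
    return replace(
        physiology,
        organ_volumes=volumes,
        organ_flows=flows,
        kidney_plasma_volume=kp,
        kidney_cell_volume=kc,
        kidney_lumen_volume=kl,
        gfr=gfr,
        excess_extracellular_water=physiology.excess_extracellular_water + excess_ecw,
    )


def apply_ckd(individual, egfr_ckd: float, stage: CKDStage | int,
              excess_ecw: float | None = None):
    """Transform a healthy virtual individual into a CKD individual.

    Sets the absolute GFR from the normalized eGFR and the individual BSA,
    multiplies the OAT3/NPT1 activity multipliers by the intact-nephron
    factor, the DPEP1 multiplier by the stage factor, and applies the
    physiology deltas of :func:`scale_physiology` (stage 5 additionally
    carries the interdialytic fluid overload, configurable via
    ``excess_ecw``).
    """
    st = stage if isinstance(stage, CKDStage) else CKDStage(stage)
    if not st.contains(egfr_ckd):
        raise DomainError(
            f"eGFR {egfr_ckd} outside stage-{st.stage} range {st.egfr_range}"
        )
    if excess_ecw is None:
        excess_ecw = STAGE5_EXCESS_ECW if st.stage == 5 else 0.0
    factor = transporter_scaling_factor(egfr_ckd)
    dpep1 = dpep1_scaling_factor(st)
    mult = dict(individual.activity_multipliers)
    mult["OAT3"] = mult.get("OAT3", 1.0) * factor
    mult["NPT1"] = mult.get("NPT1", 1.0) * factor
    mult["DPEP1"] = mult.get("DPEP1", 1.0) * dpep1
    return replace(
        individual,
        physiology=scale_physiology(individual.physiology, egfr_ckd, excess_ecw=excess_ecw),
        activity_multipliers=mult,
        egfr=egfr_ckd,
        stage=st.stage,
    )
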