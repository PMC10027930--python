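"""Drug-specific and physiology-specific input parameters.

Houses the validated parameter containers (physicochemistry and plasma
binding, Michaelis-Menten transport/metabolism processes, reference-male
anatomy), the packaged meropenem parameter file, and the tissue:plasma
partition-coefficient calculation used by the perfusion-limited model.

Internal units are µmol/L, L and min; external I/O uses mg/L and h with
molecular-weight conversion.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

from .config import ConfigurationError, load_yaml, packaged_config

#: eGFR of the reference adult male (mL/min/1.73 m²); renal-secretion
#: scaling in chronic kidney disease is expressed relative to this value.
EGFR_NORMAL = 106.78

PROCESS_NAMES = ("DPEP1", "OAT3", "NPT1")
PROCESS_DIRECTIONS = ("uptake_basolateral", "efflux_apical", "metabolism_intracellular")
BINDING_PARTNERS = ("albumin", "AGP", "none")


class ValidationError(ValueError):
    """A parameter value violates a model invariant."""


@dataclass(frozen=True)
class DrugParameters:
    """Physicochemistry and binding of the modelled drug.

    ``gfr_fraction`` multiplies glomerular filtration of unbound drug
    (1.0 = freely filtered).
    """

    name: str
    molecular_weight: float  # g/mol
    pka_acid: float | None
    pka_base: float | None
    logp: float
    water_solubility: float  # mg/mL
    fu: float  # fraction unbound in plasma, (0, 1]
    binding_partner: str
    gfr_fraction: float

    def __post_init__(self):
        if not self.molecular_weight > 0:
            raise ValidationError("molecular_weight must be positive")
        if not (0 < self.fu <= 1):
            raise ValidationError(f"fu must be in (0, 1], got {self.fu}")
        if self.gfr_fraction < 0:
            raise ValidationError("gfr_fraction must be non-negative")
        if self.binding_partner not in BINDING_PARTNERS:
            raise ValidationError(f"unknown binding partner {self.binding_partner!r}")

    @property
    def logd74(self) -> float:
        """logD at pH 7.4 from logP and the acid/base pKa values."""
        shift = 1.0
        if self.pka_acid is not None:
            shift += 10.0 ** (7.4 - self.pka_acid)
        if self.pka_base is not None:
            shift += 10.0 ** (self.pka_base - 7.4)
        return self.logp - math.log10(shift)

    def mg_to_umol(self, mg):
        return mg / self.molecular_weight * 1000.0

    def umol_to_mg(self, umol):
        return umol * self.molecular_weight / 1000.0


@dataclass(frozen=True)
class MichaelisMentenProcess:
    """A saturable renal transport or metabolism process.

    ``vmax`` is expressed as µmol/L/min referenced to ``reference_volume``
    (an effective volume absorbing tissue-expression scaling, so that
    ``vmax × reference_volume`` is the maximal amount rate in µmol/min and
    ``vmax × reference_volume / km`` the linear-range intrinsic clearance in
    L/min).  ``activity_multiplier`` is where disease scaling and transporter
    inhibition act.
    """

    name: str
    km: float  # µmol/L
    vmax: float  # µmol/L/min referenced to reference_volume
    direction: str
    reference_volume: float  # L
    activity_multiplier: float = 1.0

    def __post_init__(self):
        if self.name not in PROCESS_NAMES:
            raise ValidationError(f"unknown process {self.name!r}")
        if self.direction not in PROCESS_DIRECTIONS:
            raise ValidationError(f"unknown direction {self.direction!r}")
        if not self.km > 0:
            raise ValidationError(f"{self.name}: km must be positive")
        if self.vmax < 0:
            raise ValidationError(f"{self.name}: vmax must be non-negative")
        if not (0 <= self.activity_multiplier <= 1):
            raise ValidationError(f"{self.name}: activity_multiplier must be in [0, 1]")
        if not self.reference_volume > 0:
            raise ValidationError(f"{self.name}: reference_volume must be positive")

    @property
    def intrinsic_clearance(self) -> float:
        """Linear-range intrinsic clearance vmax·Vref/Km (L/min), including activity."""
        return self.activity_multiplier * self.vmax * self.reference_volume / self.km

    def rate(self, conc_umol_l: float) -> float:
        """Amount rate (µmol/min) at substrate concentration ``conc_umol_l``."""
        c = max(conc_umol_l, 0.0)
        return self.activity_multiplier * self.vmax * self.reference_volume * c / (self.km + c)


# organs of the perfusion-limited body; the kidney is handled mechanistically
PERFUSED_ORGANS = (
    "lung",
    "heart",
    "brain",
    "muscle",
    "adipose",
    "skin",
    "bone",
    "liver",
    "gut",
    "spleen",
    "kidney",
    "rest",
)


@dataclass(frozen=True)
class PhysiologyParameters:
    """Organ volumes (L), organ plasma flows (L/min) and renal anatomy.

    Flows are plasma flows; ``cardiac_output`` is the plasma cardiac output
    and equals the sum of the systemic organ flows (the lung is perfused in
    series with the full cardiac output).  The kidney is represented by
    vascular-plasma, proximal-tubule-cell and tubular-lumen sub-volumes.
    """

    organ_volumes: dict  # organ -> L (kidney entry = sum of its sub-volumes)
    organ_flows: dict  # organ (except lung) -> plasma flow, L/min
    kidney_plasma_volume: float  # L
    kidney_cell_volume: float  # L
    kidney_lumen_volume: float  # L
    venous_plasma_volume: float  # L
    arterial_plasma_volume: float  # L
    hematocrit: float
    gfr: float  # mL/min (absolute, individual)
    body_weight: float  # kg
    height: float  # cm
    body_surface_area: float  # m²
    #: fluid-overload extracellular water (L) in rapid equilibrium with
    #: plasma; 0 in health, expanded in end-stage renal disease
    excess_extracellular_water: float = 0.0

    def __post_init__(self):
        for organ in PERFUSED_ORGANS:
            if organ not in self.organ_volumes:
                raise ValidationError(f"missing volume for organ {organ!r}")
            if not self.organ_volumes[organ] > 0:
                raise ValidationError(f"volume of {organ!r} must be positive")
            if organ != "lung":
                if organ not in self.organ_flows:
                    raise ValidationError(f"missing plasma flow for organ {organ!r}")
                if not self.organ_flows[organ] > 0:
                    raise ValidationError(f"plasma flow of {organ!r} must be positive")
        for name in ("kidney_plasma_volume", "kidney_cell_volume", "kidney_lumen_volume",
                     "venous_plasma_volume", "arterial_plasma_volume"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if not (0 < self.hematocrit < 1):
            raise ValidationError("hematocrit must be in (0, 1)")
        if self.gfr < 0:
            raise ValidationError("gfr must be non-negative")
        if self.excess_extracellular_water < 0:
            raise ValidationError("excess_extracellular_water must be non-negative")

    @property
    def cardiac_output(self) -> float:
        """Plasma cardiac output (L/min) = sum of systemic organ plasma flows."""
        return float(sum(self.organ_flows.values()))

    @property
    def gfr_l_min(self) -> float:
        return self.gfr / 1000.0

    @property
    def egfr(self) -> float:
        """GFR normalized to 1.73 m² BSA (mL/min/1.73 m²)."""
        return self.gfr * 1.73 / self.body_surface_area


def body_surface_area(weight_kg: float, height_cm: float) -> float:
    """Du Bois body surface area (m²)."""
    return 0.007184 * weight_kg**0.425 * height_cm**0.725


_UNIT_TO_UM = {"m": 1e6, "mm": 1e3, "mM": 1e3, "um": 1.0, "µm": 1.0, "uM": 1.0, "µM": 1.0, "nm": 1e-3, "nM": 1e-3}


def _km_to_umol_l(value) -> float:
    """Normalize a Km given as number (µmol/L) or string like '3.56 mM'."""
    if isinstance(value, (int, float)):
        return float(value)
    m = re.fullmatch(r"\s*([0-9.eE+-]+)\s*([munµ]?[mM])\s*", str(value))
    if not m:
        raise ConfigurationError(f"cannot parse Km value {value!r}")
    mag, unit = float(m.group(1)), m.group(2)
    key = unit if unit in _UNIT_TO_UM else unit.lower()
    if key not in _UNIT_TO_UM:
        raise ConfigurationError(f"unknown concentration unit {unit!r}")
    return mag * _UNIT_TO_UM[key]


def load_drug_parameters(source) -> tuple[DrugParameters, list[MichaelisMentenProcess]]:
    """Load and validate a drug parameter file (YAML path or dict).

    Returns the physicochemical/binding parameters and the list of
    Michaelis-Menten processes with units normalized to µmol/L, L and min.
    """
    data = load_yaml(source)
    try:
        d = data["drug"]
    except KeyError:
        raise ConfigurationError("missing top-level key 'drug'")
    required = ["molecular_weight_g_mol", "logp", "water_solubility_mg_ml",
                "fu", "binding_partner", "gfr_fraction"]
    for key in required:
        if key not in d:
            raise ConfigurationError(f"missing drug parameter {key!r}")
    drug = DrugParameters(
        name=d.get("name", "unnamed"),
        molecular_weight=float(d["molecular_weight_g_mol"]),
        pka_acid=None if d.get("pka_acid") is None else float(d["pka_acid"]),
        pka_base=None if d.get("pka_base") is None else float(d["pka_base"]),
        logp=float(d["logp"]),
        water_solubility=float(d["water_solubility_mg_ml"]),
        fu=float(d["fu"]),
        binding_partner=str(d["binding_partner"]),
        gfr_fraction=float(d["gfr_fraction"]),
    )
    processes = []
    for p in data.get("processes", []):
        for key in ("name", "km", "vmax_umol_l_min", "direction", "reference_volume_l"):
            if key not in p:
                raise ConfigurationError(f"missing process key {key!r}")
        processes.append(
            MichaelisMentenProcess(
                name=p["name"],
                km=_km_to_umol_l(p["km"]),
                vmax=float(p["vmax_umol_l_min"]),
                direction=p["direction"],
                reference_volume=float(p["reference_volume_l"]),
                activity_multiplier=float(p.get("activity_multiplier", 1.0)),
            )
        )
    return drug, processes


def serialize_drug_parameters(drug: DrugParameters, processes) -> dict:
    """Inverse of :func:`load_drug_parameters` (Km emitted in µmol/L)."""
    return {
        "drug": {
            "name": drug.name,
            "molecular_weight_g_mol": drug.molecular_weight,
            "pka_acid": drug.pka_acid,
            "pka_base": drug.pka_base,
            "logp": drug.logp,
            "water_solubility_mg_ml": drug.water_solubility,
            "fu": drug.fu,
            "binding_partner": drug.binding_partner,
            "gfr_fraction": drug.gfr_fraction,
        },
        "processes": [
            {
                "name": p.name,
                "km": p.km,
                "vmax_umol_l_min": p.vmax,
                "direction": p.direction,
                "reference_volume_l": p.reference_volume,
                "activity_multiplier": p.activity_multiplier,
            }
            for p in processes
        ],
    }


def meropenem_parameters() -> tuple[DrugParameters, list[MichaelisMentenProcess]]:
    """The packaged meropenem parameter set."""
    return load_drug_parameters(packaged_config("meropenem.yaml"))


def reference_adult() -> PhysiologyParameters:
    """Reference adult male physiology (30 y, 176 cm, 73 kg).

    Organ volumes and blood-flow fractions follow standard reference-male
    physiology compilations; the absolute GFR corresponds to an eGFR of
    106.78 mL/min/1.73 m² at the individual's Du Bois body surface area.
    """
    data = load_yaml(packaged_config("physiology_reference.yaml"))
    return physiology_from_config(data)


def physiology_from_config(data: dict, weight: float | None = None,
                           height: float | None = None) -> PhysiologyParameters:
    """Build a physiology from a reference table, optionally rescaled.

    Volumes and flows scale linearly with body weight relative to the
    reference weight; GFR tracks the individual BSA at the reference eGFR.
    """
    ref_w = float(data["body_weight_kg"])
    w = ref_w if weight is None else float(weight)
    h = float(data["height_cm"]) if height is None else float(height)
    scale = w / ref_w
    hct = float(data["hematocrit"])
    co_plasma = float(data["cardiac_output_blood_l_min"]) * (1 - hct) * scale
    fractions = data["flow_fractions"]
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ConfigurationError("flow fractions must sum to 1")
    volumes = {k: float(v) * scale for k, v in data["organ_volumes_l"].items()}
    flows = {k: float(f) * co_plasma for k, f in fractions.items()}
    kid = data["kidney_subvolumes_l"]
    kv = {k: float(v) * scale for k, v in kid.items()}
    volumes["kidney"] = kv["plasma"] + kv["proximal_tubule_cell"] + kv["tubular_lumen"]
    bsa = body_surface_area(w, h)
    gfr = float(data["egfr_ml_min_1_73"]) * bsa / 1.73
    return PhysiologyParameters(
        organ_volumes=volumes,
        organ_flows=flows,
        kidney_plasma_volume=kv["plasma"],
        kidney_cell_volume=kv["proximal_tubule_cell"],
        kidney_lumen_volume=kv["tubular_lumen"],
        venous_plasma_volume=float(data["venous_plasma_l"]) * scale,
        arterial_plasma_volume=float(data["arterial_plasma_l"]) * scale,
        hematocrit=hct,
        gfr=gfr,
        body_weight=w,
        height=h,
        body_surface_area=bsa,
    )


# Tissue composition fractions: water, neutral lipid, phospholipid,
# extracellular water (volume fractions of wet tissue weight), from standard
# compilations used by composition-based partition methods.
TISSUE_COMPOSITION = {
    #            fW     fNL     fPL     fEW
    "lung":    (0.811, 0.0030, 0.0090, 0.336),
    "heart":   (0.758, 0.0115, 0.0166, 0.320),
    "brain":   (0.770, 0.0510, 0.0565, 0.162),
    "muscle":  (0.760, 0.0238, 0.0072, 0.091),
    "adipose": (0.180, 0.7900, 0.0020, 0.135),
    "skin":    (0.718, 0.0284, 0.0111, 0.382),
    "bone":    (0.439, 0.0740, 0.0011, 0.100),
    "liver":   (0.745, 0.0348, 0.0252, 0.161),
    "gut":     (0.718, 0.0487, 0.0163, 0.282),
    "spleen":  (0.788, 0.0201, 0.0198, 0.207),
    "kidney":  (0.783, 0.0207, 0.0162, 0.273),
    "rest":    (0.730, 0.0400, 0.0100, 0.180),
}
PLASMA_COMPOSITION = (0.945, 0.0023, 0.0013)  # fW, fNL, fPL

#: fraction of intracellular water slowly accessible to strongly ionized
#: hydrophilic drugs; 0.2 reproduces the measured interstitial penetration
#: of β-lactams (muscle tissue:plasma ratios around 0.25) and a
#: carbapenem-like steady-state distribution volume near 0.27 L/kg
SLOW_WATER_ACCESS = 0.2


def partition_coefficients(drug: DrugParameters, physiology: PhysiologyParameters) -> dict:
    """Tissue:plasma partition coefficients for the perfusion-limited organs.

    Composition-based scheme: lipid partitioning is driven by the olive-oil
    surrogate 10^logD(7.4) applied to neutral lipid plus 30% of phospholipid,
    the remaining 70% of phospholipid behaving like water.  For strongly
    ionized hydrophilic drugs (logD7.4 < -1, e.g. β-lactams) the aqueous
    tissue space accessible to drug is restricted to extracellular water
    plus a small slowly-equilibrating share of cell water
    (:data:`SLOW_WATER_ACCESS`), reproducing their extracellular-like
    distribution volumes and measured tissue penetration; otherwise total
    tissue water is used.  The residual plasma-binding correction uses a
    50% tissue-binding assumption (negligible for weakly bound drugs).

    Coefficients are independent of organ volumes (scale-free).
    """
    if drug.fu <= 0:
        raise ValidationError("fu must be positive to compute partition coefficients")
    d = 10.0 ** drug.logd74
    restricted = drug.logd74 < -1.0
    fw_p, fnl_p, fpl_p = PLASMA_COMPOSITION
    denom = d * (fnl_p + 0.3 * fpl_p) + (fw_p + 0.7 * fpl_p)
    fu_t = 1.0 / (1.0 + 0.5 * (1.0 - drug.fu) / drug.fu)
    binding_term = drug.fu / fu_t
    kps = {}
    for organ in PERFUSED_ORGANS:
        fw, fnl, fpl = TISSUE_COMPOSITION[organ][:3]
        few = TISSUE_COMPOSITION[organ][3]
        aqueous = few + SLOW_WATER_ACCESS * (fw - few) if restricted else fw
        num = d * (fnl + 0.3 * fpl) + (aqueous + 0.7 * fpl)
        kps[organ] = (num / denom) * binding_term
    return kps


def with_activity(processes, multipliers: dict) -> list:
    """Return processes with activity multipliers replaced per name."""
    out = []
    for p in processes:
        if p.name in multipliers:
            out.append(replace(p, activity_multiplier=float(multipliers[p.name])))
        else:
            out.append(p)
    return out


def with_vmax(processes, vmax_by_name: dict) -> list:
    """Return processes with Vmax values replaced per name (calibration)."""
    out = []
    for p in processes:
        if p.name in vmax_by_name:
            out.append(replace(p, vmax=float(vmax_by_name[p.name])))
        else:
            out.append(p)
    return out
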