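"""Whole-body perfusion-limited PBPK model with a mechanistic kidney.

The body is a set of well-stirred organ compartments connected by plasma
flows (lung in series between venous and arterial plasma; gut and spleen
draining through the liver).  The kidney is resolved into a vascular-plasma
space, a proximal-tubule-cell space and a tubular lumen: unbound drug is
filtered at GFR into the lumen, taken up from kidney plasma into the cell
by OAT3, effluxed from cell to lumen by NPT1 and metabolized inside the
cell by DPEP1 (all Michaelis-Menten); the lumen drains irreversibly to a
urine sink with the filtrate flow.  An optional dialyzer clearance drains
arterial plasma to a dialyzed sink during hemodialysis sessions.

Internal units: µmol (amounts), L, min.  The external interface uses mg,
mg/L and hours.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .drug_physiology import (
    DrugParameters,
    MichaelisMentenProcess,
    PhysiologyParameters,
    ValidationError,
    partition_coefficients,
)

STATE_NAMES = (
    "venous_plasma",
    "arterial_plasma",
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
    "rest",
    "kidney_plasma",
    "proximal_tubule_cell",
    "tubular_lumen",
    "urine",
    "metabolized",
    "dialyzed",
)
N_STATES = len(STATE_NAMES)
IDX = {name: i for i, name in enumerate(STATE_NAMES)}
_BODY_SLICE = slice(0, IDX["urine"])  # everything that is still "in the body"
_SIMPLE_ORGANS = ("heart", "brain", "muscle", "adipose", "skin", "bone", "rest")

#: minimal lumen drain flow (L/min); keeps the urine sink defined in
#: severe oliguria without a discontinuity at GFR -> 0
MIN_LUMEN_FLOW = 1e-4


class IntegrationError(RuntimeError):
    """The stiff solver failed to converge on a segment."""


class StructuralError(ValueError):
    """Inconsistent model/state layout."""


@dataclass(frozen=True)
class SolverSettings:
    rtol: float = 1e-8
    atol: float = 1e-10  # µmol
    method: str = "LSODA"
    grid_dt_h: float = 0.05


_REGIMEN_RE = re.compile(
    r"\s*(?P<dose>[0-9.]+)\s*(?P<unit>mg|g)\s+q(?P<iv>[0-9.]+)h"
    r"(?:\s+x(?P<n>\d+))?(?:\s+inf\s+(?P<inf>[0-9.]+)h)?\s*"
)


@dataclass(frozen=True)
class DosingRegimen:
    """Repeated zero-order intravenous infusion schedule."""

    dose_amount: float  # mg per administration
    interval: float  # h
    infusion_duration: float  # h
    n_doses: int = 1
    label: str = ""

    def __post_init__(self):
        if not self.dose_amount >= 0:
            raise ValidationError("dose_amount must be non-negative")
        if self.dose_amount > 0 and not (0 < self.infusion_duration <= self.interval):
            raise ValidationError("need 0 < infusion_duration <= interval")
        if self.n_doses < 1:
            raise ValidationError("n_doses must be >= 1")

    @classmethod
    def parse(cls, text: str) -> "DosingRegimen":
        """Parse strings like ``"1000mg q8h x7 inf 0.5h"``."""
        m = _REGIMEN_RE.fullmatch(text)
        if not m:
            raise ValidationError(f"cannot parse regimen {text!r}")
        dose = float(m.group("dose")) * (1000.0 if m.group("unit") == "g" else 1.0)
        return cls(
            dose_amount=dose,
            interval=float(m.group("iv")),
            infusion_duration=float(m.group("inf") or 0.5),
            n_doses=int(m.group("n") or 1),
            label=text.strip(),
        )

    @property
    def total_dose(self) -> float:
        return self.dose_amount * self.n_doses

    @property
    def daily_dose(self) -> float:
        return self.dose_amount * (24.0 / self.interval)

    def infusion_windows(self):
        """List of (start_h, end_h, rate_mg_h) windows."""
        out = []
        for k in range(self.n_doses):
            s = k * self.interval
            if self.dose_amount > 0:
                out.append((s, s + self.infusion_duration, self.dose_amount / self.infusion_duration))
        return out

    @property
    def last_infusion_end(self) -> float:
        if self.dose_amount == 0:
            return 0.0
        return (self.n_doses - 1) * self.interval + self.infusion_duration


@dataclass
class ConcentrationProfile:
    """Sampled plasma concentrations and cumulative elimination amounts."""

    times: np.ndarray  # h, strictly increasing
    plasma_concentration: np.ndarray  # mg/L (venous plasma, total drug)
    cumulative_urine_amount: np.ndarray  # mg
    cumulative_metabolized_amount: np.ndarray  # mg
    cumulative_dialyzed_amount: np.ndarray  # mg
    body_amount: np.ndarray | None = None  # mg still in the body
    infused_amount: np.ndarray | None = None  # mg administered up to t

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size < 1 or np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        self.times = t
        for name in ("plasma_concentration", "cumulative_urine_amount",
                     "cumulative_metabolized_amount", "cumulative_dialyzed_amount"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != t.shape:
                raise ValidationError(f"{name} has wrong shape")
            if np.any(arr < -1e-9 * max(1.0, arr.max(initial=0.0))):
                raise ValidationError(f"{name} has negative values")
            arr = np.clip(arr, 0.0, None)
            if name != "plasma_concentration":
                dec = np.diff(arr)
                if np.any(dec < -1e-6 * max(1.0, arr[-1])):
                    raise ValidationError(f"{name} must be non-decreasing")
                arr = np.maximum.accumulate(arr)
            setattr(self, name, arr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "conc_mg_L": self.plasma_concentration,
                "urine_mg": self.cumulative_urine_amount,
                "metabolized_mg": self.cumulative_metabolized_amount,
                "dialyzed_mg": self.cumulative_dialyzed_amount,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ConcentrationProfile":
        df = pd.read_csv(path)
        return cls(
            times=df["time_h"].to_numpy(),
            plasma_concentration=df["conc_mg_L"].to_numpy(),
            cumulative_urine_amount=df["urine_mg"].to_numpy(),
            cumulative_metabolized_amount=df["metabolized_mg"].to_numpy(),
            cumulative_dialyzed_amount=df["dialyzed_mg"].to_numpy(),
        )


class PBPKModel:
    """Right-hand side and state layout for one individual."""

    def __init__(self, drug: DrugParameters, processes, physiology: PhysiologyParameters,
                 kps: dict | None = None):
        self.drug = drug
        self.physiology = physiology
        self.kps = kps if kps is not None else partition_coefficients(drug, physiology)
        by_name = {p.name: p for p in processes}
        missing = set(("OAT3", "NPT1", "DPEP1")) - set(by_name)
        if missing:
            raise StructuralError(f"missing renal processes: {sorted(missing)}")
        self.oat3: MichaelisMentenProcess = by_name["OAT3"]
        self.npt1: MichaelisMentenProcess = by_name["NPT1"]
        self.dpep1: MichaelisMentenProcess = by_name["DPEP1"]
        self.processes = [by_name[n] for n in ("DPEP1", "OAT3", "NPT1")]

        phys = physiology
        self._co = phys.cardiac_output
        # fluid-overload extracellular water equilibrates rapidly with plasma
        # and is lumped into the venous pool (free fraction ~ plasma water)
        self._v_ven = phys.venous_plasma_volume + phys.excess_extracellular_water
        self._v_art = phys.arterial_plasma_volume
        self._v_lung = phys.organ_volumes["lung"]
        self._kp_lung = self.kps["lung"]
        self._simple_idx = np.array([IDX[o] for o in _SIMPLE_ORGANS])
        self._simple_q = np.array([phys.organ_flows[o] for o in _SIMPLE_ORGANS])
        self._simple_vkp = np.array(
            [phys.organ_volumes[o] * self.kps[o] for o in _SIMPLE_ORGANS]
        )
        self._q_gut = phys.organ_flows["gut"]
        self._q_spleen = phys.organ_flows["spleen"]
        self._q_ha = phys.organ_flows["liver"]
        self._q_liv = self._q_ha + self._q_gut + self._q_spleen
        self._vkp_gut = phys.organ_volumes["gut"] * self.kps["gut"]
        self._vkp_spleen = phys.organ_volumes["spleen"] * self.kps["spleen"]
        self._vkp_liv = phys.organ_volumes["liver"] * self.kps["liver"]
        self._q_kid = phys.organ_flows["kidney"]
        self._v_kp = phys.kidney_plasma_volume
        self._v_cell = phys.kidney_cell_volume
        self._v_lumen = phys.kidney_lumen_volume
        self._gfr = phys.gfr_l_min  # L/min
        self._filt_cl = drug.gfr_fraction * self._gfr * drug.fu  # L/min
        self._k_drain = max(self._gfr, MIN_LUMEN_FLOW) / self._v_lumen  # 1/min
        self._fu = drug.fu

    # -- derived quantities used by the reduced engine and diagnostics -----
    @property
    def renal_plasma_flow(self) -> float:
        return self._q_kid

    @property
    def filtration_clearance(self) -> float:
        """fu x gfr_fraction x GFR, L/min."""
        return self._filt_cl

    @property
    def uptake_intrinsic_clearance(self) -> float:
        """Linear-range OAT3 uptake clearance referenced to unbound plasma, L/min."""
        return self.oat3.intrinsic_clearance * self._fu

    def steady_state_volume(self) -> float:
        """Plasma-referenced distribution volume Vp + sum(Vt x Kp), L."""
        v = self._v_ven + self._v_art + self._v_kp + self._v_lumen
        v += self._v_lung * self._kp_lung
        v += float(np.sum(self._simple_vkp))
        v += self._vkp_gut + self._vkp_spleen + self._vkp_liv
        return v

    def rhs(self, t, y, infusion_umol_min: float, clhd_l_min: float):
        dy = np.zeros(N_STATES)
        c_ven = y[0] / self._v_ven
        c_art = y[1] / self._v_art
        c_lung_out = y[2] / (self._v_lung * self._kp_lung)
        # lung in series
        dy[2] = self._co * (c_ven - c_lung_out)
        dial = clhd_l_min * c_art
        dy[1] = self._co * (c_lung_out - c_art) - dial
        dy[18] = dial
        # simple venous-draining organs
        c_out = y[self._simple_idx] / self._simple_vkp
        dy[self._simple_idx] = self._simple_q * (c_art - c_out)
        venous_in = float(np.sum(self._simple_q * c_out))
        # splanchnic organs draining through the liver
        c_gut = y[10] / self._vkp_gut
        c_spleen = y[11] / self._vkp_spleen
        c_liv = y[9] / self._vkp_liv
        dy[10] = self._q_gut * (c_art - c_gut)
        dy[11] = self._q_spleen * (c_art - c_spleen)
        dy[9] = self._q_ha * c_art + self._q_gut * c_gut + self._q_spleen * c_spleen - self._q_liv * c_liv
        venous_in += self._q_liv * c_liv
        # mechanistic kidney
        c_kp = y[13] / self._v_kp
        filt = self._filt_cl * c_kp
        cu = self._fu * c_kp
        oat3 = self.oat3.rate(cu)
        c_cell = y[14] / self._v_cell
        npt1 = self.npt1.rate(c_cell)
        dpep1 = self.dpep1.rate(c_cell)
        dy[13] = self._q_kid * (c_art - c_kp) - filt - oat3
        dy[14] = oat3 - npt1 - dpep1
        drain = self._k_drain * y[15]
        dy[15] = filt + npt1 - drain
        dy[16] = drain
        dy[17] = dpep1
        venous_in += self._q_kid * c_kp
        dy[0] = venous_in - self._co * c_ven + infusion_umol_min
        return dy


def build_model(drug: DrugParameters, processes, physiology: PhysiologyParameters) -> PBPKModel:
    """Assemble the ODE right-hand side and state layout for one individual."""
    return PBPKModel(drug, processes, physiology)


def _segment_boundaries(regimen: DosingRegimen, t_end: float, sessions):
    pts = {0.0, t_end}
    for s, e, _ in regimen.infusion_windows():
        if s < t_end:
            pts.add(s)
            pts.add(min(e, t_end))
    for s, e in sessions or []:
        if e > t_end:
            raise ValidationError(f"dialysis session ({s}, {e}) extends past the horizon {t_end}")
        pts.add(s)
        pts.add(e)
    return sorted(pts)


def simulate_regimen(
    model: PBPKModel,
    regimen: DosingRegimen,
    t_end: float,
    sessions=None,
    clhd_l_min: float = 0.0,
    solver: SolverSettings = SolverSettings(),
    initial_state: np.ndarray | None = None,
) -> ConcentrationProfile:
    """Simulate an infusion regimen; times in hours, output in mg units.

    ``sessions`` is an optional list of (start_h, end_h) dialysis windows
    during which an additional elimination flux ``clhd_l_min x C_arterial``
    drains to the dialyzed sink.  Integration is restarted at every infusion
    and dialysis on/off boundary.
    """
    if t_end < regimen.last_infusion_end:
        raise ValidationError("t_end must cover the last infusion")
    windows = regimen.infusion_windows()
    boundaries = _segment_boundaries(regimen, t_end, sessions)
    grid = np.arange(0.0, t_end + 0.5 * solver.grid_dt_h, solver.grid_dt_h)
    grid = grid[grid <= t_end]
    for bpt in boundaries:  # boundaries win over nearby grid points
        grid = grid[np.abs(grid - bpt) > 1e-9]
    out_times = np.unique(np.concatenate([grid, np.array(boundaries)]))

    mg_to_umol = model.drug.mg_to_umol
    y = np.zeros(N_STATES) if initial_state is None else np.asarray(initial_state, float).copy()
    if y.shape != (N_STATES,):
        raise StructuralError("initial state has wrong length")

    all_t = [np.array([0.0])]
    all_y = [y.reshape(-1, 1).copy()]
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        mid = 0.5 * (a + b)
        rate_mg_h = sum(r for (s, e, r) in windows if s <= mid < e)
        hd_on = any(s <= mid < e for (s, e) in (sessions or []))
        inf_umol_min = mg_to_umol(rate_mg_h) / 60.0
        clhd = clhd_l_min if hd_on else 0.0
        # boundaries are members of out_times, so t_eval always ends at b
        t_eval = out_times[(out_times > a + 1e-12) & (out_times <= b + 1e-12)]
        sol = solve_ivp(
            model.rhs,
            (a * 60.0, b * 60.0),
            y,
            method=solver.method,
            t_eval=t_eval * 60.0,  # integrate in minutes
            args=(inf_umol_min, clhd),
            rtol=solver.rtol,
            atol=solver.atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"solver failed on segment [{a}, {b}] h: {sol.message}"
            )
        y = sol.y[:, -1].copy()
        all_t.append(sol.t / 60.0)
        all_y.append(sol.y)
    times = np.concatenate(all_t)
    states = np.concatenate(all_y, axis=1)
    order = np.argsort(times)
    times = times[order]
    states = states[:, order]
    uniq = np.concatenate([[True], np.diff(times) > 1e-12])
    times = times[uniq]
    states = np.clip(states[:, uniq], 0.0, None)

    umol_to_mg = model.drug.umol_to_mg
    conc = umol_to_mg(states[0] / model._v_ven)
    infused = np.zeros_like(times)
    for s, e, r in windows:
        infused += r * np.clip(np.minimum(times, e) - s, 0.0, None)
    return ConcentrationProfile(
        times=times,
        plasma_concentration=conc,
        cumulative_urine_amount=umol_to_mg(states[IDX["urine"]]),
        cumulative_metabolized_amount=umol_to_mg(states[IDX["metabolized"]]),
        cumulative_dialyzed_amount=umol_to_mg(states[IDX["dialyzed"]]),
        body_amount=umol_to_mg(states[_BODY_SLICE].sum(axis=0)),
        infused_amount=infused,
    )


def mass_balance(profile: ConcentrationProfile, dose: float | None = None) -> float:
    """Worst-case relative mass-balance error over all output points.

    |body + urine + metabolized + dialyzed - administered| / total dose.
    """
    if profile.body_amount is None or profile.infused_amount is None:
        raise ValidationError("profile lacks the body/infused bookkeeping series")
    total = dose if dose is not None else float(profile.infused_amount[-1])
    if total <= 0:
        return 0.0
    accounted = (
        profile.body_amount
        + profile.cumulative_urine_amount
        + profile.cumulative_metabolized_amount
        + profile.cumulative_dialyzed_amount
    )
    return float(np.max(np.abs(accounted - profile.infused_amount)) / total)


def urinary_fraction(profile: ConcentrationProfile, dose: float) -> float:
    """Fraction of the administered dose excreted unchanged in urine."""
    return float(profile.cumulative_urine_amount[-1] / dose)
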