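"""Pseudo-observed clinical datasets for pipeline testing.

The clinical concentration-time profiles the model is qualified against in
practice are digitized from literature and cannot be shipped; this module
generates datasets with the same structure (sparse sampling grids, short
infusions, healthy / CKD / dialysis settings) by simulating a study design
through the PBPK model and applying multiplicative log-normal observation
noise (default CV 15%) plus optional digitization jitter on the sampling
times (±0.05 h).  With noise off, a dataset equals the model prediction
exactly, so round-trip evaluation yields MRD = GMFE = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hemodialysis import DialysisSettings, dialyzer_clearance
from .pbpk_core import DosingRegimen, simulate_regimen
from .population import archetype, build_individual_model

#: sparse sampling grid typical of digitized single-dose studies (h)
SPARSE_GRID = (0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0)


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class StudyDesign:
    """A pseudo-study: regimen, population setting and sampling grid."""

    label: str
    regimen: DosingRegimen
    sampling_times: tuple  # h
    population: str = "healthy"  # healthy | ckd3 | ckd4 | ckd5 | ihd
    egfr: float | None = None  # CKD/IHD archetype eGFR
    dialysis: DialysisSettings | None = None
    noise_cv: float = 0.15
    time_jitter: float = 0.05  # h
    seed: int = 0
    n_subjects: int = 12  # reported metadata only (profiles are study means)

    def horizon(self) -> float:
        h = max(self.sampling_times)
        if self.dialysis is not None:
            h = max(h, max(e for _, e in self.dialysis.sessions()))
        return max(h, self.regimen.last_infusion_end)

    def individual(self):
        if self.population == "healthy":
            return archetype()
        if self.population in ("ckd3", "ckd4", "ckd5"):
            return archetype(stage=int(self.population[-1]), egfr=self.egfr)
        if self.population == "ihd":
            return archetype(stage=5, egfr=self.egfr if self.egfr is not None else 8.0)
        raise DesignError(f"unknown population {self.population!r}")


def generate_study(design: StudyDesign, drug, processes, noise: bool = True,
                   seed: int | None = None):
    """Simulate a design and emit the pseudo-observed dataset.

    Returns ``(frame, metadata)``: a tidy frame with columns study, time_h,
    conc_mg_L, urine_mg and a metadata dict (dose, infusion time,
    population, n).  Reproducible under the design's stored seed.
    """
    times = np.asarray(design.sampling_times, dtype=float)
    if np.any(np.diff(times) <= 0) or times[0] < 0:
        raise DesignError("sampling grid must be strictly increasing and non-negative")
    horizon = design.horizon()
    if times[-1] > horizon:
        raise DesignError("sampling grid outside the simulation horizon")
    ind = design.individual()
    model = build_individual_model(ind, drug, processes)
    sessions = design.dialysis.sessions() if design.dialysis else None
    clhd = dialyzer_clearance(design.dialysis) / 1000.0 if design.dialysis else 0.0
    profile = simulate_regimen(model, design.regimen, horizon,
                               sessions=sessions, clhd_l_min=clhd)
    rng = np.random.default_rng(design.seed if seed is None else seed)
    t_obs = times.copy()
    conc = np.interp(times, profile.times, profile.plasma_concentration)
    urine = np.interp(times, profile.times, profile.cumulative_urine_amount)
    if noise:
        if design.time_jitter > 0:
            t_obs = np.sort(times + rng.uniform(-design.time_jitter, design.time_jitter, times.size))
            t_obs = np.clip(t_obs, 0.0, horizon)
            conc = np.interp(t_obs, profile.times, profile.plasma_concentration)
            urine = np.interp(t_obs, profile.times, profile.cumulative_urine_amount)
        if design.noise_cv > 0:
            sigma = math.sqrt(math.log(1.0 + design.noise_cv**2))
            conc = conc * rng.lognormal(-0.5 * sigma**2, sigma, conc.size)
    frame = pd.DataFrame(
        {
            "study": design.label,
            "time_h": t_obs,
            "conc_mg_L": conc,
            "urine_mg": urine,
        }
    )
    metadata = {
        "study": design.label,
        "dose_mg": design.regimen.dose_amount,
        "infusion_h": design.regimen.infusion_duration,
        "interval_h": design.regimen.interval,
        "n_doses": design.regimen.n_doses,
        "population": design.population,
        "egfr": design.egfr,
        "noise_cv": design.noise_cv if noise else 0.0,
        "seed": design.seed if seed is None else seed,
        "n": design.n_subjects,
    }
    return frame, metadata


def _reg(dose_mg, inf_h, interval=24.0, n=1, label=""):
    return DosingRegimen(dose_amount=dose_mg, interval=interval,
                         infusion_duration=inf_h, n_doses=n, label=label)


def fixture_suite() -> list:
    """Packaged pseudo-study designs spanning the qualification settings.

    Healthy single-dose designs at several doses and infusion times, CKD
    stages 3-5, and two distinct dialysis parameter settings.
    """
    day_grid = SPARSE_GRID + (12.0, 24.0)
    ckd_grid = (0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0, 36.0, 48.0)
    ihd_grid = (0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0, 36.0, 48.0)
    hd_a = DialysisSettings(bfr=200.0, dfr=500.0, koa=188.0,
                            session_duration=4.0, session_starts=(1.0,))
    hd_b = DialysisSettings(bfr=300.0, dfr=500.0, koa=188.0,
                            session_duration=3.5, session_starts=(1.0,))
    return [
        StudyDesign("healthy_500mg_30min", _reg(500.0, 0.5, label="500 mg / 30 min"),
                    day_grid, seed=101),
        StudyDesign("healthy_1000mg_30min", _reg(1000.0, 0.5, label="1000 mg / 30 min"),
                    day_grid, seed=102),
        StudyDesign("healthy_1000mg_3h", _reg(1000.0, 3.0, label="1000 mg / 3 h"),
                    (0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0), seed=103),
        StudyDesign("ckd3_500mg_30min", _reg(500.0, 0.5, label="500 mg / 30 min"),
                    ckd_grid, population="ckd3", egfr=45.0, seed=104),
        StudyDesign("ckd4_1000mg_3h", _reg(1000.0, 3.0, label="1000 mg / 3 h"),
                    ckd_grid, population="ckd4", egfr=23.0, seed=105),
        StudyDesign("ckd5_500mg_30min", _reg(500.0, 0.5, label="500 mg / 30 min"),
                    ckd_grid, population="ckd5", egfr=8.0, seed=106),
        StudyDesign("ihd_500mg_bfr200", _reg(500.0, 0.5, label="500 mg / 30 min"),
                    ihd_grid, population="ihd", egfr=8.0, dialysis=hd_a, seed=107),
        StudyDesign("ihd_1000mg_bfr300", _reg(1000.0, 0.5, label="1000 mg / 30 min"),
                    ihd_grid, population="ihd", egfr=8.0, dialysis=hd_b, seed=108),
    ]
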