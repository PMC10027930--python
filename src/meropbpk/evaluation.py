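"""Model-qualification metrics and local sensitivity analysis.

MRD (mean relative deviation) is the log-domain RMS fold error of
concentration predictions, 10^sqrt(mean((log10 pred - log10 obs)^2)); GMFE
(geometric mean fold error) is 10^mean(|log10(pred/obs)|) over PK
parameters.  Values <= 2 are conventionally read as adequate performance.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .drug_physiology import ValidationError, with_vmax
from .nca import auc_last
from .pbpk_core import DosingRegimen, build_model, simulate_regimen

#: fold-error threshold conventionally read as adequate model performance
ADEQUACY_THRESHOLD = 2.0


class MetricError(ValueError):
    """Non-positive values reached a log-domain metric."""


def _pairs(predicted, observed):
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.size < 1:
        raise MetricError("predicted and observed must be equal-length, non-empty")
    if np.any(p <= 0) or np.any(o <= 0):
        raise MetricError(
            "log-domain metrics require positive pairs; pre-filter values at "
            "or below the assay floor and log the excluded count"
        )
    return p, o


def filter_positive(predicted, observed, floor: float = 0.0):
    """Drop pairs with either member <= floor; returns (pred, obs, n_dropped)."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    keep = (p > floor) & (o > floor)
    return p[keep], o[keep], int(np.sum(~keep))


def mrd(predicted, observed) -> float:
    """Mean relative deviation of concentration predictions."""
    p, o = _pairs(predicted, observed)
    x = np.sqrt(np.mean((np.log10(p) - np.log10(o)) ** 2))
    return float(10.0**x)


def gmfe(predicted, observed) -> float:
    """Geometric mean fold error of PK-parameter predictions."""
    p, o = _pairs(predicted, observed)
    x = np.mean(np.abs(np.log10(p / o)))
    return float(10.0**x)


def two_fold_fraction(predicted, observed) -> float:
    """Fraction of pairs with pred/obs within [0.5, 2.0], boundaries included."""
    p, o = _pairs(predicted, observed)
    ratio = p / o
    return float(np.mean((ratio >= 1.0 / ADEQUACY_THRESHOLD) & (ratio <= ADEQUACY_THRESHOLD)))


def gof_table(predicted, observed) -> pd.DataFrame:
    """Goodness-of-fit-ready table of predictions, observations and fold errors."""
    p, o = _pairs(predicted, observed)
    return pd.DataFrame({"pred": p, "obs": o, "fold_error": np.maximum(p / o, o / p)})


# ---------------------------------------------------------------------------
# sensitivity analysis

def _perturb_logp(drug, procs, phys, f):
    return replace(drug, logp=drug.logp * f), procs, phys


def _perturb_fu(drug, procs, phys, f):
    return replace(drug, fu=min(drug.fu * f, 1.0)), procs, phys


def _perturb_gfr_fraction(drug, procs, phys, f):
    return replace(drug, gfr_fraction=drug.gfr_fraction * f), procs, phys


def _perturb_gfr(drug, procs, phys, f):
    return drug, procs, replace(phys, gfr=phys.gfr * f)


def _perturb_vmax(name):
    def inner(drug, procs, phys, f):
        return drug, with_vmax(procs, {name: next(p.vmax for p in procs if p.name == name) * f}), phys
    return inner


def _perturb_kidney_volume(drug, procs, phys, f):
    volumes = dict(phys.organ_volumes)
    kp = phys.kidney_plasma_volume * f
    kc = phys.kidney_cell_volume * f
    kl = phys.kidney_lumen_volume * f
    volumes["kidney"] = kp + kc + kl
    return drug, procs, replace(
        phys, organ_volumes=volumes, kidney_plasma_volume=kp,
        kidney_cell_volume=kc, kidney_lumen_volume=kl,
    )


def _perturb_renal_flow(drug, procs, phys, f):
    flows = dict(phys.organ_flows)
    delta = flows["kidney"] * (f - 1.0)
    flows["kidney"] = flows["kidney"] * f
    flows["rest"] = flows["rest"] - delta  # conserve cardiac output
    if flows["rest"] <= 0:
        raise ValidationError("renal-flow perturbation exhausts the rest-organ flow")
    return drug, procs, replace(phys, organ_flows=flows)


PARAMETER_REGISTRY = {
    "logp": _perturb_logp,
    "fu": _perturb_fu,
    "gfr_fraction": _perturb_gfr_fraction,
    "gfr": _perturb_gfr,
    "oat3_vmax": _perturb_vmax("OAT3"),
    "npt1_vmax": _perturb_vmax("NPT1"),
    "dpep1_vmax": _perturb_vmax("DPEP1"),
    "kidney_volume": _perturb_kidney_volume,
    "renal_plasma_flow": _perturb_renal_flow,
}


def sensitivity_analysis(
    drug,
    processes,
    physiology,
    regimen: DosingRegimen | None = None,
    parameters=None,
    perturbation: float = 0.1,
    t_end: float = 24.0,
) -> dict:
    """Normalized local sensitivity of AUC_last to model parameters.

    S = (dAUC/AUC) / (dp/p), central difference with a relative step of
    ``perturbation`` (default 10%).  A failed perturbed simulation is
    reported as NaN for that parameter rather than aborting the analysis.
    """
    if regimen is None:
        regimen = DosingRegimen(dose_amount=500.0, interval=24.0, infusion_duration=0.5,
                                n_doses=1, label="500 mg / 30 min")
    names = list(parameters) if parameters is not None else list(PARAMETER_REGISTRY)
    base = simulate_regimen(build_model(drug, processes, physiology), regimen, t_end)
    auc0 = auc_last(base)
    out = {}
    for name in names:
        if name not in PARAMETER_REGISTRY:
            raise KeyError(f"unknown sensitivity parameter {name!r}")
        fn = PARAMETER_REGISTRY[name]
        try:
            aucs = []
            for f in (1.0 + perturbation, 1.0 - perturbation):
                d, pr, ph = fn(drug, processes, physiology, f)
                prof = simulate_regimen(build_model(d, pr, ph), regimen, t_end)
                aucs.append(auc_last(prof))
            out[name] = float((aucs[0] - aucs[1]) / auc0 / (2.0 * perturbation))
        except Exception:
            out[name] = float("nan")
    return out
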