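"""Qualify the model against the pseudo-observed study suite.

Generates the noisy fixture studies (healthy, CKD 3-5, two dialysis
settings), compares model predictions with the pseudo-observations via
MRD, per-study GMFE of AUC_last and Cmax, and the two-fold fraction, and
runs the local sensitivity analysis of AUC_last in the healthy and
end-stage models.

Writes results/evaluation_metrics.json and results/sensitivity.csv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from meropbpk.drug_physiology import meropenem_parameters, with_vmax
from meropbpk.evaluation import (
    gmfe, gof_table, mrd, sensitivity_analysis, two_fold_fraction,
)
from meropbpk.hemodialysis import dialyzer_clearance
from meropbpk.nca import auc_last, cmax_tmax
from meropbpk.pbpk_core import simulate_regimen
from meropbpk.population import archetype, build_individual_model
from meropbpk.synthetic_data import fixture_suite, generate_study

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
OUT.mkdir(exist_ok=True)

drug, processes = meropenem_parameters()
cal = OUT / "calibration.json"
if cal.exists():
    processes = with_vmax(processes, json.loads(cal.read_text())["parameters"])

pred_all, obs_all = [], []
auc_pred, auc_obs, cmax_pred, cmax_obs = [], [], [], []
for design in fixture_suite():
    frame, _ = generate_study(design, drug, processes, noise=True)
    model = build_individual_model(design.individual(), drug, processes)
    sessions = design.dialysis.sessions() if design.dialysis else None
    clhd = dialyzer_clearance(design.dialysis) / 1000.0 if design.dialysis else 0.0
    prof = simulate_regimen(model, design.regimen, design.horizon(),
                            sessions=sessions, clhd_l_min=clhd)
    pred = np.interp(frame["time_h"], prof.times, prof.plasma_concentration)
    obs = frame["conc_mg_L"].to_numpy()
    pred_all.extend(pred)
    obs_all.extend(obs)

    class _Obs:  # sampled pseudo-study as an NCA-ready profile
        times = frame["time_h"].to_numpy()
        plasma_concentration = obs

    class _Pred:
        times = frame["time_h"].to_numpy()
        plasma_concentration = pred

    auc_pred.append(auc_last(_Pred))
    auc_obs.append(auc_last(_Obs))
    cmax_pred.append(cmax_tmax(_Pred)[0])
    cmax_obs.append(cmax_tmax(_Obs)[0])

metrics = {
    "mrd_concentrations": mrd(pred_all, obs_all),
    "gmfe_auc_last": gmfe(auc_pred, auc_obs),
    "gmfe_cmax": gmfe(cmax_pred, cmax_obs),
    "two_fold_fraction": two_fold_fraction(pred_all, obs_all),
    "n_concentration_pairs": len(pred_all),
    "n_studies": len(auc_pred),
}
print({k: round(v, 3) if isinstance(v, float) else v for k, v in metrics.items()})
print("adequate (MRD and GMFE <= 2):",
      metrics["mrd_concentrations"] <= 2 and metrics["gmfe_auc_last"] <= 2
      and metrics["gmfe_cmax"] <= 2)
(OUT / "evaluation_metrics.json").write_text(json.dumps(metrics, indent=2))
gof_table(pred_all, obs_all).to_csv(OUT / "gof_table.csv", index=False)

rows = []
for label, stage, egfr in [("healthy", None, None), ("ckd5", 5, 8.0)]:
    ind = archetype(stage=stage, egfr=egfr)
    model = build_individual_model(ind, drug, processes)
    sens = sensitivity_analysis(drug, model.processes, model.physiology)
    for param, value in sens.items():
        rows.append({"setting": label, "parameter": param, "sensitivity": value})
sens_table = pd.DataFrame(rows)
sens_table.to_csv(OUT / "sensitivity.csv", index=False)
print(sens_table.pivot(index="parameter", columns="setting", values="sensitivity").round(3))
print(f"wrote {OUT/'evaluation_metrics.json'}, {OUT/'gof_table.csv'}, {OUT/'sensitivity.csv'}")
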