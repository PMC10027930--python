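"""Monte-Carlo dose evaluation for the CKD stages (100% fT>MIC target).

For each CKD stage, samples a virtual population, evaluates the stage's
dosing panel (conventional 30-min and prolonged 3-h infusions) across the
MIC grid at the 100% fT>MIC target over a steady dosing day, and picks the
optimal regimen per MIC (PTA >= 90%, lowest daily dose).

Writes results/pta_ckd.csv and results/optimal_ckd.csv.
"""

import json
from pathlib import Path

import pandas as pd

from meropbpk.drug_physiology import meropenem_parameters, with_vmax
from meropbpk.population import PopulationSpec, generate_population
from meropbpk.pta import MIC_GRID_CKD, NO_REGIMEN, PDTarget, evaluate_regimen_grid, optimal_regimen
from meropbpk.regimens import ckd_regimens

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
OUT.mkdir(exist_ok=True)
SEED = 42
N = 5000

drug, processes = meropenem_parameters()
cal = OUT / "calibration.json"
if cal.exists():
    processes = with_vmax(processes, json.loads(cal.read_text())["parameters"])

target = [PDTarget(1.00, (48.0, 72.0), label="steady dosing day")]
tables, optima = [], []
for stage in (3, 4, 5):
    pop = generate_population(PopulationSpec(n=N, stage=stage, seed=SEED + stage))
    grid = evaluate_regimen_grid(pop, drug, processes, ckd_regimens(stage),
                                 MIC_GRID_CKD, target, t_end=72.0, seed=SEED)
    grid.insert(0, "stage", stage)
    tables.append(grid)
    for mic in MIC_GRID_CKD:
        optima.append({"stage": stage, "mic_mg_L": mic,
                       "optimal": optimal_regimen(grid, mic)})

table = pd.concat(tables)
table.to_csv(OUT / "pta_ckd.csv", index=False)
opt = pd.DataFrame(optima)
opt.to_csv(OUT / "optimal_ckd.csv", index=False)
for stage in (3, 4, 5):
    sub = table[table["stage"] == stage]
    print(f"-- CKD stage {stage} (100% fT>MIC, n={N}) --")
    print(sub.pivot_table(index="regimen", columns="mic_mg_L",
                          values="pta_pct").round(1).to_string())
print(opt.to_string(index=False))
print(f"wrote {OUT/'pta_ckd.csv'} and {OUT/'optimal_ckd.csv'}")
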