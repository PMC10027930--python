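"""Build the healthy-adult meropenem PBPK model and characterize its PK.

Simulates single 500 mg / 30 min and 1000 mg / 3 h infusions in the
reference adult, runs non-compartmental analysis, and reports the mass
balance and the urinary / metabolized dose fractions of the uncalibrated
(literature-parameter) model.

Writes results/healthy_profiles.csv and results/healthy_nca.csv.
"""

from pathlib import Path

import pandas as pd

from meropbpk.drug_physiology import meropenem_parameters
from meropbpk.nca import nca_table
from meropbpk.pbpk_core import DosingRegimen, mass_balance, simulate_regimen
from meropbpk.population import archetype, build_individual_model

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

drug, processes = meropenem_parameters()
model = build_individual_model(archetype(), drug, processes)
print(f"Reference adult: Vss = {model.steady_state_volume():.1f} L, "
      f"GFR = {model.physiology.gfr:.1f} mL/min")

profiles = {}
frames = []
for label, regimen in [
    ("500mg_30min", DosingRegimen(500.0, 24.0, 0.5, label="500 mg / 30 min")),
    ("1000mg_3h", DosingRegimen(1000.0, 24.0, 3.0, label="1000 mg / 3 h")),
]:
    prof = simulate_regimen(model, regimen, 24.0)
    profiles[label] = prof
    fe = prof.cumulative_urine_amount[-1] / regimen.dose_amount
    fm = prof.cumulative_metabolized_amount[-1] / regimen.dose_amount
    print(f"{regimen.label}: Cmax {prof.plasma_concentration.max():.1f} mg/L, "
          f"urine {fe:.1%}, metabolized {fm:.1%}, "
          f"mass-balance error {mass_balance(prof):.1e}")
    frame = prof.to_frame()
    frame.insert(0, "regimen", label)
    frames.append(frame)

pd.concat(frames).to_csv(OUT / "healthy_profiles.csv", index=False)
nca = nca_table(profiles, last_dose_end=3.0)
nca.to_csv(OUT / "healthy_nca.csv", index=False)
print(nca.round(2).to_string(index=False))
print(f"wrote {OUT/'healthy_profiles.csv'} and {OUT/'healthy_nca.csv'}")
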