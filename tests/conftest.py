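import numpy as np
import pytest

from meropbpk.calibration import CalibrationDataset, fit
from meropbpk.drug_physiology import meropenem_parameters, reference_adult, with_vmax
from meropbpk.pbpk_core import DosingRegimen, build_model, simulate_regimen
from meropbpk.synthetic_data import fixture_suite, generate_study


@pytest.fixture(scope="session")
def drug_procs():
    return meropenem_parameters()


@pytest.fixture(scope="session")
def physiology():
    return reference_adult()


@pytest.fixture(scope="session")
def healthy_model(drug_procs, physiology):
    drug, procs = drug_procs
    return build_model(drug, procs, physiology)


@pytest.fixture(scope="session")
def regimen_500():
    return DosingRegimen(500.0, 24.0, 0.5, label="500 mg / 30 min")


@pytest.fixture(scope="session")
def profile_500(healthy_model, regimen_500):
    return simulate_regimen(healthy_model, regimen_500, 24.0)


def healthy_calibration_datasets(drug, procs):
    """Noise-free pseudo-observed healthy studies used for calibration."""
    datasets = []
    for design in [d for d in fixture_suite() if d.population == "healthy"]:
        frame, _ = generate_study(design, drug, procs, noise=False)
        datasets.append(
            CalibrationDataset(
                regimen=design.regimen,
                times=frame["time_h"].to_numpy(),
                conc=frame["conc_mg_L"].to_numpy(),
                urine=frame["urine_mg"].to_numpy(),
                label=design.label,
            )
        )
    return datasets


@pytest.fixture(scope="session")
def calibrated(drug_procs):
    """Calibrated parameter set: fit of the renal Vmax values against the
    noise-free healthy studies plus the 70% urinary-excretion constraint."""
    drug, procs = drug_procs
    datasets = healthy_calibration_datasets(drug, procs)
    bounds = {p.name: (0.2 * p.vmax, 5.0 * p.vmax) for p in procs}
    result = fit(bounds, datasets, drug, procs, budget=120, seed=1)
    return drug, with_vmax(procs, result.parameters), result
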