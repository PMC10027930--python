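import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meropbpk.config import ConfigurationError
from meropbpk.drug_physiology import (
    DrugParameters,
    TISSUE_COMPOSITION,
    PLASMA_COMPOSITION,
    ValidationError,
    load_drug_parameters,
    partition_coefficients,
    serialize_drug_parameters,
)


class TestPackagedMeropenemConfig:
    """The packaged parameter file reproduces the published input values."""

    def test_physicochemistry(self, drug_procs):
        drug, _ = drug_procs
        assert drug.molecular_weight == 383.46
        assert drug.pka_acid == 3.47
        assert drug.pka_base == 9.39
        assert drug.logp == 1.25
        assert drug.water_solubility == 5.63
        assert drug.fu == 0.98
        assert drug.binding_partner == "albumin"
        assert drug.gfr_fraction == 1.00

    @pytest.mark.parametrize(
        "name, km, vmax",
        [("DPEP1", 3560.0, 79.34), ("OAT3", 847.0, 18156.72), ("NPT1", 755.89, 57.64)],
    )
    def test_kinetics_normalized_to_umol_l(self, drug_procs, name, km, vmax):
        _, procs = drug_procs
        p = next(p for p in procs if p.name == name)
        assert p.km == pytest.approx(km)  # mM / µM inputs normalized
        assert p.vmax == pytest.approx(vmax)

    def test_round_trip_six_significant_digits(self, drug_procs):
        drug, procs = drug_procs
        data = serialize_drug_parameters(drug, procs)
        drug2, procs2 = load_drug_parameters(data)
        assert drug2.molecular_weight == pytest.approx(drug.molecular_weight, rel=1e-6)
        assert drug2.fu == pytest.approx(drug.fu, rel=1e-6)
        for a, b in zip(procs, procs2):
            assert b.km == pytest.approx(a.km, rel=1e-6)
            assert b.vmax == pytest.approx(a.vmax, rel=1e-6)


class TestValidation:
    def test_negative_vmax_rejected(self, drug_procs):
        drug, procs = drug_procs
        data = serialize_drug_parameters(drug, procs)
        data["processes"][0]["vmax_umol_l_min"] = -1.0
        with pytest.raises(ValidationError):
            load_drug_parameters(data)

    def test_missing_key_names_the_key(self, drug_procs):
        drug, procs = drug_procs
        data = serialize_drug_parameters(drug, procs)
        del data["drug"]["fu"]
        with pytest.raises(ConfigurationError, match="fu"):
            load_drug_parameters(data)

    def test_fu_outside_unit_interval_rejected(self, drug_procs):
        drug, _ = drug_procs
        with pytest.raises(ValidationError):
            replace(drug, fu=0.0)
        with pytest.raises(ValidationError):
            replace(drug, fu=1.2)


class TestReferenceAdult:
    def test_demographics(self, physiology):
        assert physiology.body_weight == 73.0
        assert physiology.height == 176.0

    def test_egfr_normalization(self, physiology):
        assert physiology.egfr == pytest.approx(106.78, rel=1e-9)

    def test_flow_conservation(self, physiology):
        total = sum(physiology.organ_flows.values())
        assert total == pytest.approx(physiology.cardiac_output, rel=1e-6)


class TestPartitionCoefficients:
    def test_neutral_drug_tracks_tissue_water(self, physiology):
        """With unit partitioning and no binding, low-lipid organs sit at
        their tissue-water:plasma-water ratio (lipid-rich organs gain the
        lipid term of the composition scheme)."""
        drug = DrugParameters(
            name="probe", molecular_weight=300.0, pka_acid=None, pka_base=None,
            logp=0.0, water_solubility=1.0, fu=1.0, binding_partner="none",
            gfr_fraction=1.0,
        )
        kps = partition_coefficients(drug, physiology)
        fw_p = PLASMA_COMPOSITION[0]
        for organ, kp in kps.items():
            fw, fnl = TISSUE_COMPOSITION[organ][0], TISSUE_COMPOSITION[organ][1]
            if fnl < 0.05:  # water-dominated tissues
                assert kp == pytest.approx(fw / fw_p, rel=0.15)

    def test_halving_fu_decreases_all_coefficients(self, drug_procs, physiology):
        drug, _ = drug_procs
        base = partition_coefficients(drug, physiology)
        low = partition_coefficients(replace(drug, fu=drug.fu / 2), physiology)
        for organ in base:
            assert low[organ] < base[organ]

    def test_scale_free_in_organ_volumes(self, drug_procs, physiology):
        drug, _ = drug_procs
        scaled = replace(
            physiology,
            organ_volumes={k: 2 * v for k, v in physiology.organ_volumes.items()},
        )
        assert partition_coefficients(drug, physiology) == partition_coefficients(drug, scaled)

    @settings(max_examples=30, deadline=None)
    @given(logp=st.floats(-4, 5), fu=st.floats(0.01, 1.0))
    def test_always_positive(self, logp, fu):
        from meropbpk.drug_physiology import reference_adult

        phys = reference_adult()
        drug = DrugParameters(
            name="probe", molecular_weight=300.0, pka_acid=None, pka_base=None,
            logp=logp, water_solubility=1.0, fu=fu, binding_partner="none",
            gfr_fraction=1.0,
        )
        assert all(v > 0 for v in partition_coefficients(drug, phys).values())
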