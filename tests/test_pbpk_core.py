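import numpy as np
import pytest

from meropbpk.drug_physiology import ValidationError, with_activity
from meropbpk.nca import auc_last
from meropbpk.pbpk_core import (
    ConcentrationProfile,
    DosingRegimen,
    N_STATES,
    SolverSettings,
    build_model,
    mass_balance,
    simulate_regimen,
)


class TestDosingRegimen:
    def test_parse(self):
        r = DosingRegimen.parse("1000mg q8h x7 inf 0.5h")
        assert (r.dose_amount, r.interval, r.n_doses, r.infusion_duration) == (1000.0, 8.0, 7, 0.5)
        assert DosingRegimen.parse("0.5g q12h").dose_amount == 500.0

    def test_infusion_longer_than_interval_rejected(self):
        with pytest.raises(ValidationError):
            DosingRegimen(500.0, 8.0, 9.0)

    def test_daily_dose(self):
        assert DosingRegimen(500.0, 12.0, 0.5).daily_dose == 1000.0


class TestModelStructure:
    def test_rhs_zero_at_origin(self, healthy_model):
        dy = healthy_model.rhs(0.0, np.zeros(N_STATES), 0.0, 0.0)
        assert np.all(dy == 0.0)

    def test_no_entry_route_no_urine(self, drug_procs, physiology):
        from dataclasses import replace

        drug, procs = drug_procs
        procs0 = with_activity(procs, {"OAT3": 0.0})
        model = build_model(drug, procs0, replace(physiology, gfr=0.0))
        prof = simulate_regimen(model, DosingRegimen(500.0, 24.0, 0.5), 12.0)
        assert np.all(prof.cumulative_urine_amount == 0.0)

    def test_zero_dose_gives_zero_profile(self, healthy_model):
        prof = simulate_regimen(healthy_model, DosingRegimen(0.0, 24.0, 0.5), 6.0)
        assert np.all(prof.plasma_concentration == 0.0)
        assert np.all(prof.cumulative_urine_amount == 0.0)


class TestSimulation:
    def test_mass_balance_below_1e6(self, profile_500):
        assert mass_balance(profile_500) < 1e-6

    def test_concentrations_non_negative(self, profile_500):
        assert np.all(profile_500.plasma_concentration >= 0.0)

    def test_low_dose_linearity(self, drug_procs, physiology):
        """At peak concentrations far below every Km, AUC doubles with dose."""
        drug, procs = drug_procs
        model = build_model(drug, procs, physiology)
        aucs = []
        for dose in (50.0, 100.0):
            prof = simulate_regimen(model, DosingRegimen(dose, 24.0, 0.5), 24.0)
            peak_umol = drug.mg_to_umol(prof.plasma_concentration.max())
            assert peak_umol < 0.05 * min(p.km for p in procs)
            aucs.append(auc_last(prof))
        assert aucs[1] / aucs[0] == pytest.approx(2.0, rel=0.02)

    def test_tolerance_refinement_stable(self, healthy_model, regimen_500):
        coarse = simulate_regimen(healthy_model, regimen_500, 24.0)
        fine = simulate_regimen(
            healthy_model, regimen_500, 24.0,
            solver=SolverSettings(rtol=1e-10, atol=1e-12),
        )
        mask = coarse.plasma_concentration > 1e-6
        rel = np.abs(fine.plasma_concentration[mask] - coarse.plasma_concentration[mask])
        rel /= coarse.plasma_concentration[mask]
        assert rel.max() < 1e-3

    def test_urine_monotone_in_oat3_activity(self, drug_procs, physiology):
        """More basolateral uptake means faster urinary excretion.  Once the
        dose is fully eliminated the DPEP1 share caps the urinary total, so
        the clean monotonicity statement is early-time cumulative urine in
        the full model and all-time cumulative urine with metabolism off."""
        drug, procs = drug_procs
        early, total_no_dpep1 = [], []
        for mult in (0.2, 0.6, 1.0):
            model = build_model(drug, with_activity(procs, {"OAT3": mult}), physiology)
            prof = simulate_regimen(model, DosingRegimen(500.0, 24.0, 0.5), 24.0)
            early.append(np.interp(2.0, prof.times, prof.cumulative_urine_amount))
            model2 = build_model(
                drug, with_activity(procs, {"OAT3": mult, "DPEP1": 0.0}), physiology
            )
            prof2 = simulate_regimen(model2, DosingRegimen(500.0, 24.0, 0.5), 24.0)
            total_no_dpep1.append(prof2.cumulative_urine_amount[-1])
        assert early[0] <= early[1] <= early[2]
        assert total_no_dpep1[0] <= total_no_dpep1[1] <= total_no_dpep1[2]

    def test_t_end_before_infusion_end_rejected(self, healthy_model):
        with pytest.raises(ValidationError):
            simulate_regimen(healthy_model, DosingRegimen(500.0, 24.0, 3.0), 2.0)


class TestProfileContainer:
    def test_csv_round_trip(self, profile_500, tmp_path):
        path = tmp_path / "profile.csv"
        profile_500.to_csv(path)
        back = ConcentrationProfile.from_csv(path)
        np.testing.assert_allclose(back.times, profile_500.times)
        np.testing.assert_allclose(back.plasma_concentration, profile_500.plasma_concentration)

    def test_rejects_unsorted_times(self):
        with pytest.raises(ValidationError):
            ConcentrationProfile(
                times=np.array([0.0, 2.0, 1.0]),
                plasma_concentration=np.zeros(3),
                cumulative_urine_amount=np.zeros(3),
                cumulative_metabolized_amount=np.zeros(3),
                cumulative_dialyzed_amount=np.zeros(3),
            )

    def test_rejects_decreasing_cumulative_series(self):
        with pytest.raises(ValidationError):
            ConcentrationProfile(
                times=np.array([0.0, 1.0, 2.0]),
                plasma_concentration=np.zeros(3),
                cumulative_urine_amount=np.array([0.0, 5.0, 1.0]),
                cumulative_metabolized_amount=np.zeros(3),
                cumulative_dialyzed_amount=np.zeros(3),
            )
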