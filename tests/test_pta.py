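import numpy as np
import pandas as pd
import pytest

from meropbpk.pbpk_core import DosingRegimen, simulate_regimen
from meropbpk.population import PopulationSpec, build_individual_model, generate_population
from meropbpk.pta import (
    NO_REGIMEN,
    DomainError,
    PDTarget,
    evaluate_regimen_grid,
    ft_above_mic,
    optimal_regimen,
    pta,
)
from meropbpk.reduced import reduce_population, simulate_reduced, time_above_threshold
from meropbpk.regimens import default_ihd_settings, ihd_regimens, ihd_windows


class _Profile:
    def __init__(self, times, conc):
        self.times = np.asarray(times, dtype=float)
        self.plasma_concentration = np.asarray(conc, dtype=float)


class TestFtAboveMic:
    def test_always_above(self):
        p = _Profile([0, 12, 24], [20, 20, 20])
        assert ft_above_mic(p, 8.0, 0.98, (0, 24)) == 1.0

    def test_never_above(self):
        p = _Profile([0, 12, 24], [4, 4, 4])
        assert ft_above_mic(p, 8.0, 0.98, (0, 24)) == 0.0

    def test_monoexponential_crossing_matches_closed_form(self):
        k = 0.4
        t = np.arange(0, 24.001, 0.05)
        c = 32.0 * np.exp(-k * t)
        fu, mic = 0.98, 8.0
        t_cross = np.log(fu * 32.0 / mic) / k
        est = ft_above_mic(_Profile(t, c), mic, fu, (0, 24))
        assert est * 24.0 == pytest.approx(t_cross, abs=0.05)

    def test_strictly_above_not_at_equality(self):
        p = _Profile([0, 24], [8.0 / 0.98] * 2)  # free concentration == MIC
        assert ft_above_mic(p, 8.0, 0.98, (0, 24)) == 0.0

    def test_empty_window_rejected(self):
        with pytest.raises(DomainError):
            ft_above_mic(_Profile([0, 24], [1, 1]), 1.0, 1.0, (5, 5))

    def test_window_outside_span_rejected(self):
        with pytest.raises(DomainError):
            ft_above_mic(_Profile([0, 24], [1, 1]), 1.0, 1.0, (0, 48))


class TestReducedEngine:
    def test_time_above_matches_dense_numerical_integration(self, drug_procs):
        drug, procs = drug_procs
        pop = generate_population(PopulationSpec(n=40, stage=5, seed=9))
        rp = reduce_population(pop, drug, procs)
        reg = DosingRegimen(500.0, 12.0, 0.5, n_doses=14)
        sett = default_ihd_settings()
        segs = simulate_reduced(rp, reg, 168.0, sessions=sett.sessions(),
                                clhd_l_min=0.1116)
        window = (48.0, 72.0)
        exact = time_above_threshold(segs, 2.0, window)
        # brute-force check on a dense grid
        tgrid = np.linspace(window[0], window[1], 20001)
        conc = np.zeros((len(pop), tgrid.size))
        for (a, b, c0, c_inf, k_h) in segs:
            m = (tgrid >= a) & (tgrid < b)
            if m.any():
                conc[:, m] = c_inf[:, None] + (c0 - c_inf)[:, None] * np.exp(
                    -k_h[:, None] * (tgrid[m] - a)
                )
        brute = np.sum(conc > 2.0, axis=1) * (tgrid[1] - tgrid[0])
        np.testing.assert_allclose(exact, brute, atol=0.02)

    def test_reduced_agrees_with_full_pbpk(self, drug_procs):
        """Per-subject fT>MIC from the surrogate tracks the full ODE model."""
        drug, procs = drug_procs
        pop = generate_population(PopulationSpec(n=12, stage=5, seed=21))
        reg = DosingRegimen(500.0, 24.0, 0.5, n_doses=3, label="0.5 g qd")
        sett = default_ihd_settings()
        sessions = [s for s in sett.sessions() if s[1] <= 72.0]
        from meropbpk.hemodialysis import dialyzer_clearance

        clhd = dialyzer_clearance(sett) / 1000.0
        rp = reduce_population(pop, drug, procs)
        segs = simulate_reduced(rp, reg, 72.0, sessions=sessions, clhd_l_min=clhd)
        ft_red = time_above_threshold(segs, 2.0 / drug.fu, (48.0, 72.0)) / 24.0
        ft_full = []
        from meropbpk.pbpk_core import SolverSettings

        solver = SolverSettings(rtol=1e-6, atol=1e-8)
        for ind in pop:
            model = build_individual_model(ind, drug, procs)
            prof = simulate_regimen(model, reg, 72.0, sessions=sessions,
                                    clhd_l_min=clhd, solver=solver)
            ft_full.append(ft_above_mic(prof, 2.0, drug.fu, (48.0, 72.0)))
        diff = np.abs(ft_red - np.asarray(ft_full))
        assert np.median(diff) < 0.05
        assert diff.max() < 0.15


class TestPta:
    def test_all_above_gives_100(self, drug_procs):
        drug, procs = drug_procs
        pop = generate_population(PopulationSpec(n=10, stage=5, seed=2))
        reg = DosingRegimen(2000.0, 12.0, 0.5, n_doses=4)
        target = PDTarget(0.40, (0.0, 48.0), label="window")
        res = pta(pop, drug, procs, reg, 0.25, target, t_end=48.0, engine="reduced")
        assert res.pta == 100.0

    def test_deterministic_under_seed(self, drug_procs):
        drug, procs = drug_procs
        target = PDTarget(0.40, (0.0, 24.0), label="day1")
        reg = DosingRegimen(500.0, 24.0, 0.5)
        vals = []
        for _ in range(2):
            pop = generate_population(PopulationSpec(n=50, stage=5, seed=13))
            vals.append(pta(pop, drug, procs, reg, 4.0, target, t_end=24.0).pta)
        assert vals[0] == vals[1]

    def test_matches_brute_force_indicator_count(self, drug_procs):
        drug, procs = drug_procs
        pop = generate_population(PopulationSpec(n=10, stage=5, seed=17))
        reg = DosingRegimen(250.0, 24.0, 0.5, n_doses=1)
        target = PDTarget(0.40, (0.0, 24.0), label="day1")
        res = pta(pop, drug, procs, reg, 2.0, target, t_end=24.0, engine="reduced")
        rp = reduce_population(pop, drug, procs)
        segs = simulate_reduced(rp, reg, 24.0)
        ft = time_above_threshold(segs, 2.0 / drug.fu, (0.0, 24.0)) / 24.0
        assert res.pta == pytest.approx(np.mean(ft >= 0.40) * 100.0)

    def test_stricter_target_attains_less(self, drug_procs):
        drug, procs = drug_procs
        pop = generate_population(PopulationSpec(n=300, stage=5, seed=4))
        reg = DosingRegimen(500.0, 24.0, 0.5, n_doses=2)
        loose = PDTarget(0.40, (0.0, 48.0), label="w")
        strict = PDTarget(1.00, (0.0, 48.0), label="w")
        p40 = pta(pop, drug, procs, reg, 2.0, loose, t_end=48.0).pta
        p100 = pta(pop, drug, procs, reg, 2.0, strict, t_end=48.0).pta
        assert p100 <= p40

    def test_monte_carlo_error_small(self, drug_procs):
        drug, procs = drug_procs
        reg = DosingRegimen(500.0, 24.0, 0.5, n_doses=7, label="0.5 g qd")
        sett = default_ihd_settings()
        target = ihd_windows()[0]
        vals = []
        for seed in (1, 2):
            pop = generate_population(PopulationSpec(n=2000, stage=5, seed=seed))
            vals.append(pta(pop, drug, procs, reg, 4.0, target, t_end=168.0,
                            settings=sett).pta)
        assert abs(vals[0] - vals[1]) < 1.5


class TestGridAndOptimality:
    @pytest.fixture(scope="class")
    def grid(self, drug_procs):
        drug, procs = drug_procs
        pop = generate_population(PopulationSpec(n=400, stage=5, seed=5))
        return evaluate_regimen_grid(
            pop, drug, procs, ihd_regimens(), [1.0, 2.0, 4.0, 8.0],
            ihd_windows(), t_end=168.0, settings=default_ihd_settings(),
        )

    def test_monotone_in_mic(self, grid):
        for (_, _), g in grid.groupby(["regimen", "window"]):
            v = g.sort_values("mic_mg_L")["pta_pct"].to_numpy()
            assert np.all(np.diff(v) <= 1e-9)

    def test_monotone_in_dose_same_interval(self, grid):
        for window in ("on-dialysis", "off-dialysis"):
            for mic in (1.0, 2.0, 4.0, 8.0):
                sub = grid[(grid["window"] == window) & (grid["mic_mg_L"] == mic)]
                qd = sub[sub["n_daily_admin"] == 1].sort_values("daily_dose_mg")
                assert np.all(np.diff(qd["pta_pct"].to_numpy()) >= -1e-9)

    def test_optimal_regimen_prefers_lowest_daily_dose(self, grid):
        choice = optimal_regimen(grid, mic=1.0, window="off-dialysis")
        assert choice == "0.25 g once daily"

    def test_no_regimen_sentinel(self):
        table = pd.DataFrame(
            {
                "regimen": ["a", "b"],
                "window": ["w", "w"],
                "mic_mg_L": [8.0, 8.0],
                "pta_pct": [10.0, 55.0],
                "daily_dose_mg": [500.0, 1000.0],
                "n_daily_admin": [1, 2],
                "infusion_h": [0.5, 0.5],
            }
        )
        assert optimal_regimen(table, mic=8.0, window="w") == NO_REGIMEN

    def test_single_qualifier_selected(self):
        table = pd.DataFrame(
            {
                "regimen": ["a", "b"],
                "window": ["w", "w"],
                "mic_mg_L": [2.0, 2.0],
                "pta_pct": [95.0, 60.0],
                "daily_dose_mg": [3000.0, 1000.0],
                "n_daily_admin": [3, 1],
                "infusion_h": [0.5, 0.5],
            }
        )
        assert optimal_regimen(table, mic=2.0, window="w") == "a"
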