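"""Pharmacology fits, the two-step antagonism ODE, and PK-PD occupancy."""

import math

import numpy as np
import pytest

import twopocket as tp
from twopocket import assays, kinetics
from twopocket.kinetics import DegenerateDataError, KineticsError

LN2 = math.log(2.0)


class TestOnePhaseDecay:
    @pytest.mark.parametrize(
        "t_half,times",
        [
            (9.41, (0.0, 1.0, 3.0, 6.0, 24.0)),
            (0.20, (0.0, 0.25, 0.5, 1.0, 3.0)),
            (0.98, (0.0, 0.5, 1.0, 2.0, 6.0)),
        ],
    )
    def test_noiseless_recovery_is_exact(self, t_half, times):
        ds = tp.generate_washout_dataset(t_half, times, plateau=100.0, initial=0.0)
        fit = kinetics.fit_one_phase_decay(ds.x, ds.y)
        assert fit.converged
        assert fit.t_half == pytest.approx(t_half, rel=1e-6)
        assert fit.plateau == pytest.approx(100.0, rel=1e-6)

    def test_constrained_plateau(self):
        ds = tp.generate_washout_dataset(5.0, (0, 1, 2, 4, 8, 16))
        fit = kinetics.fit_one_phase_decay(ds.x, ds.y, constrain_plateau=100.0)
        assert fit.t_half == pytest.approx(5.0, rel=1e-6)
        assert fit.plateau == 100.0

    def test_constant_input_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            kinetics.fit_one_phase_decay([0, 1, 2, 3], [50.0, 50.0, 50.0, 50.0])

    def test_too_few_points(self):
        with pytest.raises(KineticsError):
            kinetics.fit_one_phase_decay([0, 1], [0.0, 10.0])


class TestLogLinearPK:
    def test_noiseless_recovery(self):
        ds = tp.generate_pk_dataset(1000.0, 6.65, (0.5, 1, 2, 4, 8, 24))
        fit = kinetics.fit_log_linear_pk(ds.x, ds.y)
        assert fit.converged
        assert fit.t_half == pytest.approx(6.65, rel=1e-9)
        assert fit.c0 == pytest.approx(1000.0, rel=1e-9)

    def test_exact_halving_gives_kel_ln2(self):
        fit = kinetics.fit_log_linear_pk([0.0, 1.0, 2.0], [100.0, 50.0, 25.0])
        assert fit.kel == pytest.approx(LN2, rel=1e-12)

    def test_increasing_concentrations_flagged(self):
        fit = kinetics.fit_log_linear_pk([0, 1, 2], [10.0, 20.0, 40.0])
        assert not fit.converged
        assert fit.t_half is None

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(KineticsError):
            kinetics.fit_log_linear_pk([0, 1, 2], [10.0, 0.0, 1.0])


class TestFourPL:
    def test_noiseless_recovery(self):
        concs = (0.1, 0.5, 1.0, 3.0, 6.4, 10.0, 30.0, 100.0, 1000.0)
        ds = tp.generate_dose_response(6.4, 1.0, 100.0, 0.0, concs)
        fit = kinetics.fit_4pl(ds.x, ds.y)
        assert fit.converged
        assert fit.ic50 == pytest.approx(6.4, rel=1e-6)
        assert fit.hill == pytest.approx(1.0, rel=1e-6)

    def test_fitted_curve_midpoint(self):
        concs = (0.5, 1.0, 3.0, 10.0, 30.0, 100.0)
        ds = tp.generate_dose_response(5.0, 1.2, 100.0, 0.0, concs)
        fit = kinetics.fit_4pl(ds.x, ds.y)
        mid = assays.four_pl(fit.ic50, fit.ic50, fit.hill, fit.top, fit.bottom)
        assert mid == pytest.approx(0.5 * (fit.top + fit.bottom), rel=1e-9)

    def test_flat_data_degenerate(self):
        with pytest.raises(DegenerateDataError):
            kinetics.fit_4pl([1, 2, 4, 8], [50.0] * 4)


class TestFitterNoiseBehaviour:
    def test_rmse_shrinks_with_noise_level(self):
        """Parameter-recovery RMSE over 200 seeded noisy datasets shrinks
        as the noise level drops (for all three fitters)."""
        times = np.array([0.0, 0.5, 1, 2, 4, 8, 12, 24.0])
        concs = (0.3, 1.0, 3.0, 6.4, 20.0, 64.0, 300.0)

        def rmse(noise):
            errs = {"decay": [], "pk": [], "4pl": []}
            for seed in range(200):
                d = tp.generate_washout_dataset(9.41, times, noise_sd=noise, seed=seed)
                f = kinetics.fit_one_phase_decay(d.x, d.y)
                if f.converged:
                    errs["decay"].append(f.t_half - 9.41)
                p = tp.generate_pk_dataset(
                    1000.0, 6.65, times[1:], noise_sd=noise / 100, seed=seed,
                    multiplicative_noise=True,
                )
                f = kinetics.fit_log_linear_pk(p.x, p.y)
                if f.converged:
                    errs["pk"].append(f.t_half - 6.65)
                q = tp.generate_dose_response(6.4, 1.0, 100.0, 0.0, concs,
                                              noise_sd=noise, seed=seed)
                f = kinetics.fit_4pl(q.x, q.y)
                if f.converged and f.ic50 < 1e3:
                    errs["4pl"].append(f.ic50 - 6.4)
            return {k: float(np.sqrt(np.mean(np.square(v)))) for k, v in errs.items()}

        noisy = rmse(5.0)
        quiet = rmse(0.5)
        for key in noisy:
            assert quiet[key] < noisy[key]
            assert quiet[key] < 0.5  # near-unbiased recovery at low noise


class TestTwoStepModel:
    def test_preset_half_lives(self):
        assert kinetics.KSI_LIKE.apparent_dissociation_half_life == pytest.approx(9.41)
        assert kinetics.W146_LIKE.apparent_dissociation_half_life == pytest.approx(0.20)
        assert kinetics.COMPOUND4_LIKE.apparent_dissociation_half_life == pytest.approx(0.98)

    def test_no_pretreatment_gives_full_emax(self):
        res = kinetics.simulate_two_step_competition(kinetics.KSI_LIKE, 0.0)
        assert res["emax"] == pytest.approx(100.0, abs=1e-6)
        assert np.allclose(res["responses"], 100.0)

    def test_surmountable_antagonist_recovers_at_long_readout(self):
        res = kinetics.simulate_two_step_competition(
            kinetics.W146_LIKE, 1000.0, readout_time=6.0
        )
        assert res["emax"] == pytest.approx(100.0, abs=1.0)

    def test_pseudoirreversible_frozen_tight_state_limit(self):
        """With k2 ≫ k−2 = 0 the tight complex formed during pretreatment
        is frozen, so Emax equals 100·(1 − tight fraction) (closed form)."""
        p = kinetics.TwoStepModelParams(
            k1=0.1, k_1=1.0, k2=50.0, k_2=0.0, agonist_kon=10.0, agonist_koff=1.0
        )
        res = kinetics.simulate_two_step_competition(
            p, 1000.0, pretreat_time=1.0, readout_time=4.0
        )
        frozen = res["species_after_pretreat"]["RI_tight"]
        assert res["emax"] == pytest.approx(100.0 * (1.0 - frozen), rel=0.02)

    def test_receptor_conservation(self):
        p = kinetics.KSI_LIKE
        res = kinetics.simulate_two_step_competition(p, 100.0)
        total = sum(res["species_after_pretreat"].values())
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_emax_decreases_with_pretreatment_for_pseudoirreversible(self):
        grid = (1.0, 10.0, 100.0, 1000.0)
        table = kinetics.emax_vs_pretreatment(kinetics.KSI_LIKE, grid)
        emax = [row["emax"] for row in table]
        assert all(a > b for a, b in zip(emax, emax[1:]))

    def test_emax_flat_for_surmountable(self):
        grid = (1.0, 10.0, 100.0, 1000.0)
        table = kinetics.emax_vs_pretreatment(
            kinetics.W146_LIKE, grid, readout_time=6.0
        )
        for row in table:
            assert row["emax"] == pytest.approx(100.0, abs=1.0)

    def test_zero_length_pretreatment(self):
        res = kinetics.simulate_two_step_competition(
            kinetics.KSI_LIKE, 1000.0, pretreat_time=0.0
        )
        assert res["emax"] == pytest.approx(100.0, abs=1e-6)

    def test_invalid_grid_rejected(self):
        with pytest.raises(KineticsError):
            kinetics.emax_vs_pretreatment(kinetics.KSI_LIKE, (10.0, 1.0))


class TestOccupancyPKPD:
    def test_pure_dissociation_closed_form(self):
        tc = kinetics.simulate_receptor_occupancy_pk(
            {"c0": 0.0, "kel": 0.1}, kon=1.0, koff=0.5, duration=10.0, occ0=1.0
        )
        assert np.allclose(tc.occupancy, np.exp(-0.5 * tc.times), atol=1e-10)

    def test_constant_exposure_langmuir_steady_state(self):
        tc = kinetics.simulate_receptor_occupancy_pk(
            {"c0": 10.0, "kel": 0.0}, kon=1.0, koff=5.0, duration=20.0
        )
        assert tc.occupancy[-1] == pytest.approx(10.0 / 15.0, abs=1e-6)

    def test_slow_dissociation_maintains_occupancy_at_32h(self):
        pk = {"c0": 100.0, "kel": LN2 / 6.65}
        slow = kinetics.simulate_receptor_occupancy_pk(pk, 0.01, LN2 / 9.41, 48.0)
        fast = kinetics.simulate_receptor_occupancy_pk(pk, 0.01, LN2 / 0.98, 48.0)
        occ32_slow = np.interp(32.0, slow.times, slow.occupancy)
        occ32_fast = np.interp(32.0, fast.times, fast.occupancy)
        assert occ32_slow > occ32_fast

    def test_terminal_occupancy_half_life_reflects_residence_time(self):
        """Slow dissociation decouples occupancy decay from plasma decay;
        fast dissociation tracks the 6.65-h exposure half-life."""
        pk = {"c0": 100.0, "kel": LN2 / 6.65}
        slow = kinetics.simulate_receptor_occupancy_pk(pk, 0.01, LN2 / 9.41, 72.0)
        fast = kinetics.simulate_receptor_occupancy_pk(pk, 0.01, LN2 / 0.98, 72.0)
        t_slow = kinetics.occupancy_terminal_half_life(slow)
        t_fast = kinetics.occupancy_terminal_half_life(fast)
        assert t_slow > 6.65 * 1.2
        assert t_fast == pytest.approx(6.65, rel=0.10)

    def test_persistence_metric_edge_cases(self):
        tc = kinetics.OccupancyTimecourse(
            times=np.linspace(0, 10, 11),
            occupancy=np.zeros(11),
            plasma_conc=np.zeros(11),
        )
        assert kinetics.persistence_metric(tc, 0.5) == 0.0
        tc.occupancy = np.ones(11)
        assert kinetics.persistence_metric(tc, 0.5) == pytest.approx(10.0)

    def test_persistence_monotone_in_residence_time(self):
        pk = {"c0": 100.0, "kel": LN2 / 6.65}
        durations = []
        for koff in (2.0, 0.7, 0.2, 0.07):
            tc = kinetics.simulate_receptor_occupancy_pk(pk, 0.01, koff, 72.0)
            durations.append(kinetics.persistence_metric(tc, 0.3))
        assert all(a <= b for a, b in zip(durations, durations[1:]))
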