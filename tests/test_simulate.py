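"""Tests of the diel forcing, the Euler stepper and multi-day runs."""

import numpy as np
import pytest

import trichoflux as tf
from trichoflux.simulate import forcing_at, step

P = tf.ModelParameters()
S = tf.ForcingSchedule()


class TestForcing:
    @pytest.mark.parametrize(
        "t, I, f_P",
        [
            (1.0, S.I_light, 0.80),    # early light, mostly photosynthetic
            (5.0, S.I_light, 0.55),    # midday shift toward N2-fixing cells
            (10.0, S.I_light, 0.80),
            (13.0, 0.0, 0.80),         # dark period
            (25.0, S.I_light, 0.80),   # wraps modulo 24 h
        ],
    )
    def test_step_function_values(self, t, I, f_P):
        f = forcing_at(S, t)
        assert f.I == I
        assert f.f_P == pytest.approx(f_P)
        assert f.f_P + f.f_N == pytest.approx(1.0)

    def test_schedules_must_cover_the_day(self):
        with pytest.raises(tf.InputDomainError):
            tf.ForcingSchedule(f_P_steps=((3.0, 0.8),))
        with pytest.raises(tf.InputDomainError):
            tf.ForcingSchedule(f_P_steps=((0.0, 1.2),))


class TestStep:
    def test_all_rates_zero_leaves_state_unchanged(self):
        frozen = P.replace(
            F_Cfix_MaxChl=0.0, F_Bio_max=0.0, F_Nfix_full=0.0,
            O2_env=0.0,
        )
        s0 = tf.StorageState(0.4, 0.05)
        s1, flux, oxy, _ = step(s0, 1.0, 0.001, frozen, S)
        assert s1.C_Sto == pytest.approx(s0.C_Sto)
        assert s1.N_Sto == pytest.approx(s0.N_Sto)
        assert flux.F_Res == pytest.approx(0.0)

    def test_dark_step_with_empty_store_keeps_it_nonnegative(self):
        s0 = tf.StorageState(0.0, 0.05)
        s1, flux, oxy, _ = step(s0, 13.0, 0.001, P, S)
        assert s1.C_Sto >= 0.0
        # respiration was limited to what fixation (none) + storage (none) allow
        assert flux.F_Res_N <= 1e-9

    def test_per_step_carbon_and_nitrogen_conservation(self):
        """Away from the limiter, the Euler increments close the budgets
        to round-off."""
        state = tf.StorageState(0.4, 0.05)
        dt = 0.001
        for t in (0.5, 4.0, 9.5, 15.0):
            new, flux, oxy, _ = step(state, t, dt, P, S)
            dc = flux.F_Cfix - flux.F_Bio - flux.F_Nfix * P.Y_Nfix_CN - flux.F_Res
            dn = flux.F_Nfix - flux.F_Bio * P.Y_Bio_NC
            assert new.C_Sto - state.C_Sto == pytest.approx(dc * dt, abs=1e-14)
            assert new.N_Sto - state.N_Sto == pytest.approx(dn * dt, abs=1e-14)
            state = new

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(tf.InputDomainError):
            step(tf.StorageState(0.4, 0.05), 1.0, 0.0, P, S)


class TestRun:
    def test_no_photosynthesis_means_no_carbon_fluxes(self):
        p = P.replace(F_Cfix_MaxChl=0.0)
        r = tf.run(p, S, days=2, dt_days=0.002, spinup_days=1,
                   initial=tf.StorageState(0.0, 0.05))
        day = r.analysis_day()
        assert day.F_Cfix.abs().max() == 0.0
        assert day.F_Bio.abs().max() == pytest.approx(0.0, abs=1e-12)

    def test_time_grid_monotone_and_congruent(self, default_run):
        t = default_run.frame.t_hours.to_numpy()
        assert (np.diff(t) > 0).all()
        assert len(default_run.frame) == default_run.days * round(1 / default_run.dt_days)

    def test_diel_periodicity_after_spinup(self, default_run):
        """After spin-up the reserves repeat with < 0.1% relative drift."""
        assert default_run.periodic
        spd = round(1 / default_run.dt_days)
        f = default_run.frame
        a = f.iloc[-2 * spd:-spd][["C_Sto", "N_Sto"]].to_numpy()
        b = f.iloc[-spd:][["C_Sto", "N_Sto"]].to_numpy()
        assert (np.abs(b - a).max(axis=0) / np.abs(a).max(axis=0) < 1e-3).all()

    def test_halving_dt_barely_moves_the_trajectory(self):
        """End-of-day reserves at the default step match a finer run."""
        init = tf.StorageState(0.3, 0.05)
        coarse = tf.run(P, S, days=1, dt_days=0.001, spinup_days=0, initial=init)
        fine = tf.run(P, S, days=1, dt_days=0.0005, spinup_days=0, initial=init)
        c0 = coarse.frame.iloc[-1].C_Sto
        c1 = fine.frame.iloc[-1].C_Sto
        assert abs(c0 - c1) / abs(c1) < 0.01
        ref = tf.run(P, S, days=1, dt_days=0.0001, spinup_days=0, initial=init)
        assert abs(c0 - ref.frame.iloc[-1].C_Sto) / abs(ref.frame.iloc[-1].C_Sto) < 0.01

    def test_midday_n2_fixation_jump_requires_cell_differentiation(self, default_run):
        """The near-doubling of N2 fixation at the hour-3 shift disappears
        when f_P is held constant at 0.8."""
        w = default_run.window
        before, after = w(2.5, 3.0).F_Nfix.mean(), w(3.0, 3.5).F_Nfix.mean()
        assert after / before > 1.7
        const = tf.ForcingSchedule(f_P_steps=((0.0, 0.8),))
        rc = tf.run(P, const, days=4)
        wc = rc.window
        ratio = wc(3.0, 3.5).F_Nfix.mean() / wc(2.5, 3.0).F_Nfix.mean()
        assert ratio < 1.1

    def test_spinup_failure_raises(self):
        # one day cannot satisfy a day-over-day periodicity check
        with pytest.raises(tf.InputDomainError):
            tf.run(P, S, days=1, spinup_days=1)
        from trichoflux.simulate import SpinupError
        with pytest.raises(SpinupError):
            tf.run(P, S, days=2, dt_days=0.002, spinup_days=1,
                   initial=tf.StorageState(2.9, 0.14),
                   require_periodic=True, periodic_tol=1e-6)

    def test_run_metadata_records_grid_and_parameters(self, default_run):
        md = default_run.metadata
        assert md["dt_days"] == default_run.dt_days
        assert md["params_hash"] == default_run.params.content_hash()
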