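"""Unit and property tests for the algebraic flux laws."""

import math

import pytest
from hypothesis import given, settings, strategies as st

import trichoflux as tf
from trichoflux.fluxes import partition_carbon_budget

P = tf.ModelParameters()


def forcing(f_P=0.8, I=200.0, t=1.0):
    return tf.ForcingState(t=t, I=I, f_P=f_P, f_N=1.0 - f_P)


class TestN2Fixation:
    @pytest.mark.parametrize(
        "O2_N, C_Sto, N_Sto, expected_factor",
        [
            # full O2 inhibition at the critical concentration
            (P.O2_crit, 0.5, 0.0, 0.0),
            # N storage full -> fixation shut off
            (0.0, 0.5, P.N_Sto_max, 0.0),
            # C storage per N cell at half saturation, other factors = 1
            (0.0, P.K_C * 0.2, 0.0, 0.5),
        ],
    )
    def test_scaling_factor_endpoints(self, O2_N, C_Sto, N_Sto, expected_factor):
        f = forcing(f_P=0.8)  # f_N = 0.2, so C_Sto/f_N = K_C in the third case
        rate = tf.n2_fixation_rate(P, tf.StorageState(C_Sto, N_Sto), f, O2_N)
        ceiling = P.F_Nfix_full * f.f_N * P.f_NITROGE
        assert rate == pytest.approx(expected_factor * ceiling, abs=1e-12)

    def test_dark_gate_zeroes_rate(self):
        storage = tf.StorageState(0.5, 0.0)
        dark = forcing(I=0.0, t=13.0)
        assert tf.n2_fixation_rate(P, storage, dark, 0.0) == 0.0
        ungated = P.replace(dark_gate_n2fix=False)
        assert tf.n2_fixation_rate(ungated, storage, dark, 0.0) > 0.0

    def test_all_photosynthetic_cells_fix_nothing(self):
        f = tf.ForcingState(t=1.0, I=200.0, f_P=1.0, f_N=0.0)
        assert tf.n2_fixation_rate(P, tf.StorageState(0.5, 0.0), f, 0.0) == 0.0

    def test_negative_oxygen_rejected(self):
        with pytest.raises(tf.InputDomainError):
            tf.n2_fixation_rate(P, tf.StorageState(0.5, 0.0), forcing(), -0.1)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        o2=st.floats(0.0, 0.05),
        c=st.floats(0.0, P.C_Sto_max),
        n=st.floats(0.0, P.N_Sto_max),
    )
    def test_bounded_and_monotone(self, o2, c, n):
        """Rate stays within its ceiling, falls with O2 and stored N,
        rises with stored C."""
        f = forcing()
        rate = tf.n2_fixation_rate(P, tf.StorageState(c, n), f, o2)
        ceiling = P.F_Nfix_full * f.f_N * P.f_NITROGE
        assert 0.0 <= rate <= ceiling + 1e-12
        assert tf.n2_fixation_rate(P, tf.StorageState(c, n), f, o2 + 0.01) <= rate + 1e-12
        more_n = min(n + 0.01, P.N_Sto_max)
        assert tf.n2_fixation_rate(P, tf.StorageState(c, more_n), f, o2) <= rate + 1e-12
        more_c = min(c + 0.1, P.C_Sto_max)
        assert tf.n2_fixation_rate(P, tf.StorageState(more_c, n), f, o2) >= rate - 1e-12


class TestBiomassProduction:
    @pytest.mark.parametrize(
        "C_Sto, N_Sto, expected",
        [
            (0.0, 0.1, 0.0),                          # no carbon, no growth
            (P.K_C, 100 * P.K_N, 0.5 * P.F_Bio_max),  # C at half saturation
            (1e6, 1e6, P.F_Bio_max),                  # saturation limit
        ],
    )
    def test_monod_endpoints(self, C_Sto, N_Sto, expected):
        rate = tf.biomass_production_rate(P, tf.StorageState(C_Sto, N_Sto))
        assert rate == pytest.approx(expected, rel=1e-6)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(c=st.floats(0.0, 10.0), n=st.floats(0.0, 1.0))
    def test_liebig_minimum_never_exceeds_single_resource(self, c, n):
        rate = tf.biomass_production_rate(P, tf.StorageState(c, n))
        c_only = P.F_Bio_max * c / (c + P.K_C)
        n_only = P.F_Bio_max * n / (n + P.K_N)
        assert rate <= min(c_only, n_only) + 1e-12


class TestCarbonFixation:
    def test_dark_and_full_storage_are_zero(self):
        assert tf.carbon_fixation_rate(P, tf.StorageState(0.5, 0.0), forcing(I=0.0)) == 0.0
        full = tf.StorageState(P.C_Sto_max, 0.0)
        assert tf.carbon_fixation_rate(P, full, forcing()) == 0.0

    def test_half_saturating_light(self):
        I_half = math.log(2) / P.K_I
        rate = tf.carbon_fixation_rate(P, tf.StorageState(0.0, 0.0),
                                       tf.ForcingState(t=1.0, I=I_half, f_P=1.0, f_N=0.0))
        assert rate == pytest.approx(0.5 * P.F_Cfix_MaxChl * P.C_Sto_max * P.Chl_full, rel=1e-9)

    def test_overfull_storage_rejected(self):
        with pytest.raises(tf.InputDomainError):
            tf.carbon_fixation_rate(P, tf.StorageState(P.C_Sto_max * 1.01, 0.0), forcing())

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        I=st.floats(0.0, 500.0),
        c=st.floats(0.0, P.C_Sto_max - 1e-6),
        fp=st.floats(0.0, 1.0),
    )
    def test_monotone_in_light_cells_and_storage(self, I, c, fp):
        f = tf.ForcingState(t=1.0, I=I, f_P=fp, f_N=1.0 - fp)
        s = tf.StorageState(c, 0.0)
        rate = tf.carbon_fixation_rate(P, s, f)
        assert rate >= 0.0
        brighter = tf.ForcingState(t=1.0, I=I + 50, f_P=fp, f_N=1.0 - fp)
        assert tf.carbon_fixation_rate(P, s, brighter) >= rate - 1e-12
        fuller = tf.StorageState(min(c + 0.1, P.C_Sto_max), 0.0)
        assert tf.carbon_fixation_rate(P, fuller, f) <= rate + 1e-12


class TestRespirationP:
    def test_linear_in_biomass_production(self):
        assert tf.respiration_P(P, 0.0) == 0.0
        y = P.replace(Y_Res_Bio=0.4)
        assert tf.respiration_P(y, 1.0) == pytest.approx(0.4)
        assert tf.respiration_P(y, 2.0) == pytest.approx(2 * tf.respiration_P(y, 1.0))


class TestCarbonBudget:
    def _fluxes(self, **kw):
        base = dict(F_Cfix=2.0, F_Bio=0.1, F_Nfix=0.05, F_Res_P=0.04,
                    F_Res_N=1.5, F_ResN2=0.0, F_RP=0.0, F_CSto=0.0, F_Nfix_C=0.1)
        base.update(kw)
        return tf.FluxSet(**base)

    def test_no_fixation_means_all_n_respiration_is_protection(self):
        b = partition_carbon_budget(P, self._fluxes(F_Nfix=0.0, F_Nfix_C=0.0), 0.3)
        assert b.F_ResN2 == 0.0
        assert b.F_RP == pytest.approx(1.5)

    def test_degenerate_all_zero_budget_is_flagged_not_nan(self):
        zero = tf.FluxSet(*[0.0] * 9)
        b = partition_carbon_budget(P, zero, 0.0)
        assert not b.valid
        assert all(v == 0.0 for v in b.fractions_total.values())

    def test_fractions_sum_to_one_under_both_normalizations(self):
        b = partition_carbon_budget(P, self._fluxes(), 0.3)
        assert sum(b.fractions_total.values()) == pytest.approx(1.0)
        assert sum(b.fractions_nonstorage.values()) == pytest.approx(1.0)
        assert b.fractions_nonstorage["F_CSto"] == 0.0

    def test_excessive_energetic_yield_rejected(self):
        bad = P.replace(Y_ResN2_Nfix=1e3)
        with pytest.raises(tf.ParameterError):
            partition_carbon_budget(bad, self._fluxes(), 0.0)


def test_fvfm_weighted_mean_endpoints():
    assert tf.fvfm(tf.ForcingState(0, 200, 1.0, 0.0), P) == pytest.approx(0.5)
    assert tf.fvfm(tf.ForcingState(0, 200, 0.0, 1.0), P) == pytest.approx(0.1)
    assert tf.fvfm(forcing(f_P=0.8), P) == pytest.approx(0.42)
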