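"""Measurement arithmetic, fits, classification logic and group statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from treskit import ephys
from treskit.simulate import DoseResponseModelSpec, predict_activity, simulate_dose_response

CONCS = [0.1, 1.0, 10.0, 30.0, 100.0, 300.0]


def _hill_fit(spec: DoseResponseModelSpec, n_replicates=1) -> ephys.HillFit:
    return ephys.fit_hill(simulate_dose_response(spec, CONCS, n_replicates))


class TestNernst:
    def test_hand_evaluated_reversal_potential(self):
        # 100 mM internal / 2 mM bath K+ at 20 C
        assert ephys.nernst_potential(100.0, 2.0, 20.0) == pytest.approx(-98.8, abs=0.1)

    def test_symmetric_solutions_reverse_at_zero(self):
        assert ephys.nernst_potential(100.0, 100.0) == 0.0


class TestMeasureCurrent:
    @staticmethod
    def _sweep(t, i):
        return pd.DataFrame({"time_ms": t, "voltage_mV": -100.0, "current_uA": i})

    def test_constant_segment_both_windows(self):
        t = np.arange(0.0, 500.0, 1.0)
        sweep = self._sweep(t, np.full(t.size, -2.0))
        assert ephys.measure_current(sweep, 0, 500, "steady_state") == -2.0
        assert ephys.measure_current(sweep, 0, 500, "tail") == -2.0

    def test_steady_state_after_fast_decay(self):
        t = np.arange(0.0, 500.0, 0.5)
        i = -1.0 + np.exp(-t / 10.0)
        sweep = self._sweep(t, i)
        measured = ephys.measure_current(sweep, 0, 500, "steady_state")
        assert abs(measured - (-1.0)) < 0.01

    def test_tail_window_must_fit_inside_segment(self):
        t = np.arange(0.0, 500.0, 1.0)
        sweep = self._sweep(t, np.zeros(t.size))
        with pytest.raises(ValueError, match="outside segment"):
            ephys.measure_current(sweep, 0, 6, "tail", tail_delay_ms=2, tail_width_ms=5)


class TestPotentiationAndActivity:
    def test_hand_computed_ratio(self):
        assert ephys.compute_potentiation(-5.0, -2.0) == pytest.approx(2.5)

    def test_no_effect_is_unity(self):
        assert ephys.compute_potentiation(-2.0, -2.0) == 1.0

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError, match="zero control"):
            ephys.compute_potentiation(-5.0, 0.0)

    def test_sign_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sign mismatch"):
            ephys.compute_potentiation(5.0, -2.0)

    def test_sub_unity_ratio_flagged(self):
        with pytest.warns(UserWarning, match="inhibition"):
            ephys.compute_potentiation(-1.0, -2.0)

    @pytest.mark.parametrize("ratio,expected", [(2.5, 150.0), (1.0, 0.0), (0.5, -50.0)])
    def test_activity_percent(self, ratio, expected):
        assert ephys.compute_activity(-2.0 * ratio, -2.0) == pytest.approx(expected)


class TestNormalizeIV:
    @staticmethod
    def _table(scale=1.0, cmp_factor=2.0):
        v = np.arange(-120, 41, 10, dtype=float)
        i = scale * 0.05 * (v + 95.0)
        ctrl = pd.DataFrame({"condition": "control", "voltage_mV": v, "current_uA": i})
        cmp_ = pd.DataFrame(
            {"condition": "compound", "voltage_mV": v, "current_uA": cmp_factor * i}
        )
        return pd.concat([ctrl, cmp_], ignore_index=True)

    def test_reference_normalizes_to_one(self):
        out = ephys.normalize_iv(self._table())
        ref = out[(out.condition == "control") & (out.voltage_mV == 40.0)]
        assert ref["current_norm"].iloc[0] == pytest.approx(1.0)

    def test_scale_invariance(self):
        a = ephys.normalize_iv(self._table(scale=1.0))
        b = ephys.normalize_iv(self._table(scale=7.3))
        np.testing.assert_allclose(a["current_norm"], b["current_norm"], rtol=1e-12)

    def test_doubled_compound_curve_doubles_normalized(self):
        out = ephys.normalize_iv(self._table(cmp_factor=2.0))
        ctrl = out[out.condition == "control"]["current_norm"].to_numpy()
        cmp_ = out[out.condition == "compound"]["current_norm"].to_numpy()
        np.testing.assert_allclose(cmp_, 2.0 * ctrl, rtol=1e-12)

    def test_missing_reference_rejected(self):
        table = self._table()
        with pytest.raises(ValueError, match="no control current"):
            ephys.normalize_iv(table[table.voltage_mV < 40.0])


class TestHillFit:
    def test_noiseless_recovery_to_machine_tolerance(self):
        fit = _hill_fit(DoseResponseModelSpec(e_max=262.0, ec50=38.0, hill=1.0))
        assert fit.converged
        assert fit.ec50 == pytest.approx(38.0, rel=1e-6)
        assert fit.e_max == pytest.approx(262.0, rel=1e-6)
        assert fit.h == pytest.approx(1.0, rel=1e-6)

    def test_half_max_identity_of_fitted_curve(self):
        fit = _hill_fit(DoseResponseModelSpec(e_max=360.0, ec50=64.0, hill=1.3))
        assert fit.predict(fit.ec50) == pytest.approx(fit.e_max / 2.0, rel=1e-9)

    def test_requires_four_distinct_concentrations(self):
        df = pd.DataFrame({"conc_uM": [1.0, 10.0, 100.0], "activity_pct": [1, 2, 3]})
        with pytest.raises(ValueError, match="4 distinct"):
            ephys.fit_hill(df)

    def test_noisy_recovery_within_fifteen_percent(self):
        errs = []
        for seed in range(25):
            spec = DoseResponseModelSpec(
                e_max=262.0, ec50=38.0, hill=1.0, replicate_noise_sd=10.0, seed=seed
            )
            fit = _hill_fit(spec, n_replicates=10)
            errs.append(abs(fit.ec50 - 38.0) / 38.0)
        assert np.median(errs) < 0.15

    def test_se_shrinks_like_inverse_sqrt_n(self):
        """log(SE_EC50) vs log(n) slope is -0.5 within 0.1 (averaged over seeds)."""
        ns = [5, 20, 80]
        mean_log_se = []
        for n in ns:
            ses = []
            for seed in range(12):
                spec = DoseResponseModelSpec(
                    e_max=262.0, ec50=38.0, hill=1.0, replicate_noise_sd=10.0, seed=seed
                )
                ses.append(_hill_fit(spec, n_replicates=n).se_ec50)
            mean_log_se.append(np.mean(np.log(ses)))
        slope = np.polyfit(np.log(ns), mean_log_se, 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)


class TestStoichiometry:
    def test_one_dead_site_classified_proportional_occupancy(self):
        ref = _hill_fit(
            DoseResponseModelSpec(
                model_kind="two_site_proportional", e_max=262.0, ec50=38.0, functional_sites=2
            )
        )
        test = _hill_fit(
            DoseResponseModelSpec(
                model_kind="two_site_proportional", e_max=262.0, ec50=38.0, functional_sites=1
            )
        )
        report = ephys.compare_stoichiometry(ref, test)
        assert report.e_max_ratio == pytest.approx(0.5, abs=1e-6)
        assert report.ec50_ratio == pytest.approx(1.0, abs=1e-6)
        assert report.classification == "proportional-occupancy"

    def test_identical_fits_classified_single_site_sufficient(self):
        fit = _hill_fit(DoseResponseModelSpec(e_max=262.0, ec50=38.0))
        report = ephys.compare_stoichiometry(fit, fit)
        assert report.e_max_ratio == pytest.approx(1.0)
        assert report.classification == "single-site-sufficient"

    def test_unconverged_input_rejected(self):
        fit = _hill_fit(DoseResponseModelSpec(e_max=262.0, ec50=38.0))
        broken = ephys.HillFit(
            e_max=1.0, ec50=1.0, h=1.0, se_e_max=None, se_ec50=None, se_h=None,
            residual_ss=0.0, n_points=6, converged=False,
        )
        with pytest.raises(ValueError, match="converged"):
            ephys.compare_stoichiometry(fit, broken)


class TestAntagonism:
    @staticmethod
    def _fits(kind, kb=20.0, levels=(0.0, 20.0, 60.0)):
        fits = []
        for b in levels:
            spec = DoseResponseModelSpec(
                model_kind=kind if b > 0 else "single_site_hill",
                e_max=300.0,
                ec50=50.0,
                antagonist_conc=b,
                antagonist_kb=kb,
            )
            fits.append(_hill_fit(spec))
        return fits, list(levels)

    def test_noncompetitive_generator_recovered(self):
        fits, levels = self._fits("noncompetitive_antagonist")
        report = ephys.classify_antagonism(fits, levels)
        assert report.classification == "noncompetitive"
        assert report.kb_noncompetitive_uM == pytest.approx(20.0, rel=1e-6)
        # E_max exactly halved at [B] = Kb, EC50 untouched
        assert fits[1].e_max == pytest.approx(150.0, rel=1e-6)
        assert fits[1].ec50 == pytest.approx(50.0, rel=1e-6)

    def test_competitive_generator_recovered(self):
        fits, levels = self._fits("competitive_antagonist")
        report = ephys.classify_antagonism(fits, levels)
        assert report.classification == "competitive"
        assert fits[1].ec50 == pytest.approx(100.0, rel=1e-6)  # Gaddum: doubled at Kb
        assert fits[1].e_max == pytest.approx(300.0, rel=1e-6)
        assert report.kb_competitive_uM == pytest.approx(20.0, rel=1e-4)

    def test_inert_antagonist_is_indeterminate(self):
        fit = _hill_fit(DoseResponseModelSpec(e_max=300.0, ec50=50.0))
        report = ephys.classify_antagonism([fit, fit, fit], [0.0, 20.0, 60.0])
        assert report.classification == "indeterminate"

    def test_fewer_than_three_levels_rejected(self):
        fit = _hill_fit(DoseResponseModelSpec())
        with pytest.raises(ValueError, match=">= 3"):
            ephys.classify_antagonism([fit, fit], [0.0, 10.0])


class TestInactivationFraction:
    def test_direct_evaluation(self):
        assert ephys.compute_FI(10.0, 8.41) == pytest.approx(15.9)

    def test_no_inactivation_is_zero(self):
        assert ephys.compute_FI(-3.2, -3.2) == 0.0

    def test_printed_group_means_give_thirty_percent_reduction(self):
        reduction = 100.0 * (1.0 - 11.1 / 15.9)
        assert round(reduction) == 30

    def test_zero_tail_rejected(self):
        with pytest.raises(ValueError, match="zero tail"):
            ephys.compute_FI(0.0, 1.0)

    @given(
        st.floats(0.1, 100.0),
        st.floats(0.0, 0.99),
        st.floats(-1000, 1000).filter(lambda k: abs(k) > 1e-6),
    )
    def test_scale_invariance(self, tail, frac, k):
        steady = tail * (1.0 - frac)
        assert ephys.compute_FI(k * tail, k * steady) == pytest.approx(
            ephys.compute_FI(tail, steady), rel=1e-9
        )


class TestGrowthFit:
    X = np.array([10.0, 20.0, 30.0, 50.0, 75.0, 100.0, 150.0, 200.0])

    def test_noiseless_exact_recovery(self):
        y = 15.9 - 15.9 * 0.98**self.X
        fit = ephys.fit_inactivation_growth(self.X, y)
        assert fit.converged
        assert fit.a == pytest.approx(15.9, rel=1e-6)
        assert fit.b == pytest.approx(15.9, rel=1e-6)
        assert fit.c == pytest.approx(0.98, rel=1e-6)
        assert 0.0 < fit.c < 1.0

    def test_constant_data_degenerates_to_flat_fit(self):
        fit = ephys.fit_inactivation_growth(self.X, np.full(self.X.size, 12.5))
        assert abs(fit.b) < 1e-6
        assert fit.a == pytest.approx(12.5, abs=1e-6)

    def test_noisy_steady_state_within_twenty_percent(self):
        errs = []
        for seed in range(25):
            rng = np.random.default_rng(seed)
            y = 15.9 - 15.9 * 0.98**self.X + rng.normal(0, 2.0, self.X.size)
            fit = ephys.fit_inactivation_growth(self.X, y)
            errs.append(abs(fit.a - 15.9) / 15.9)
        assert np.median(errs) < 0.2

    def test_too_few_durations_rejected(self):
        with pytest.raises(ValueError, match="4 inter-pulse"):
            ephys.fit_inactivation_growth([10, 20, 30], [1, 2, 3])


class TestExponentialFit:
    def test_noiseless_exact_recovery(self):
        x = np.arange(0.0, 200.0, 2.0)
        y = -1.0 + (-0.5) * np.exp(-x / 20.0)
        fit = ephys.fit_exponential_tau(x, y)
        assert fit.converged and fit.identifiable
        assert fit.a0 == pytest.approx(-1.0, rel=1e-8)
        assert fit.a1 == pytest.approx(-0.5, rel=1e-8)
        assert fit.tau == pytest.approx(20.0, rel=1e-8)

    def test_noisy_tau_within_ten_percent(self):
        x = np.arange(0.0, 200.0, 0.5)
        errs = []
        for seed in range(25):
            rng = np.random.default_rng(seed)
            y = -1.0 - 0.5 * np.exp(-x / 20.0) + rng.normal(0, 0.05, x.size)  # SNR ~ 10
            fit = ephys.fit_exponential_tau(x, y)
            errs.append(abs(fit.tau - 20.0) / 20.0)
        assert np.median(errs) < 0.10

    def test_flat_trace_flagged_unidentifiable(self):
        x = np.arange(0.0, 100.0, 1.0)
        fit = ephys.fit_exponential_tau(x, np.full(x.size, -2.0))
        assert not fit.identifiable

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="10 samples"):
            ephys.fit_exponential_tau(np.arange(5.0), np.arange(5.0))


class TestGroupStats:
    def test_textbook_anova_decomposition(self):
        report = ephys.group_stats({"a": [1, 2, 3], "b": [2, 3, 4], "c": [6, 7, 8]})
        assert report.anova_F == pytest.approx(21.0, abs=1e-10)
        assert report.anova_df == (2, 6)

    def test_textbook_pooled_t(self):
        report = ephys.group_stats({"a": [1, 2, 3], "b": [2, 3, 4]})
        assert report.t_stat == pytest.approx(-1.2247, abs=1e-4)
        assert report.t_df == 4

    def test_identical_groups_are_null(self):
        report = ephys.group_stats({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert report.anova_F == pytest.approx(0.0, abs=1e-12)
        assert report.tukey["p_adj"].iloc[0] == pytest.approx(1.0)

    def test_sem_uses_n_minus_one(self):
        report = ephys.group_stats({"a": [30.0, 30.0, 40.0], "b": [1.0, 2.0]})
        assert report.sem["a"] == pytest.approx(np.std([30, 30, 40], ddof=1) / math.sqrt(3))

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            ephys.group_stats({"a": [1.0], "b": [1.0, 2.0]})

    @given(st.floats(0.0, 1.0))
    def test_stars_match_thresholds(self, p):
        stars = ephys.significance_stars(p)
        if p < 0.001:
            assert stars == "***"
        elif p < 0.01:
            assert stars == "**"
        elif p < 0.05:
            assert stars == "*"
        else:
            assert stars == "ns"
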