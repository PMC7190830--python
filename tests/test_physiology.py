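"""Calcium normalization (dF/F0, dR/R) and four-parameter logistic fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from saltnav import (
    CalciumTrace,
    delta_f_over_f,
    delta_r_over_r,
    fit_dose_response,
    normalize_responses,
    simulate_calcium,
    simulate_calcium_fret,
    simulate_dose_response,
    summarize_responses,
)


def _trace(f, bg=0.0, onset=10.0, dt=0.1):
    f = np.asarray(f, dtype=float)
    return CalciumTrace(t=np.arange(f.size) * dt, channels={"F": f},
                        background=bg, stim_onset_s=onset)


class TestDeltaFOverF:
    def test_constant_trace_is_zero(self):
        out = delta_f_over_f(_trace(np.full(300, 80.0)))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_doubling_step_reaches_plus_100_percent(self):
        f = np.concatenate([np.full(150, 50.0), np.full(150, 100.0)])
        out = delta_f_over_f(_trace(f))
        assert out[-1] == pytest.approx(100.0)

    def test_per_sample_background_reduced_to_median(self):
        f = np.full(300, 110.0)
        bg = np.full(300, 10.0)
        bg[::7] = 14.0  # spikes; median stays 10
        out = delta_f_over_f(_trace(f, bg=bg))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_nonpositive_f0_diagnosed(self):
        with pytest.raises(ValueError, match="F0"):
            delta_f_over_f(_trace(np.full(300, 5.0), bg=10.0))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0.1, 100.0))
    def test_invariant_under_positive_gain(self, gain):
        rng = np.random.default_rng(12)
        f = 100.0 + 20.0 * rng.random(300)
        a = delta_f_over_f(_trace(f, bg=5.0))
        b = delta_f_over_f(_trace(f * gain, bg=5.0 * gain))
        np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-9)


class TestDeltaROverR:
    def _fret(self, cfp, yfp, onset=10.0, dt=0.1):
        n = len(cfp)
        return CalciumTrace(t=np.arange(n) * dt,
                            channels={"CFP": np.asarray(cfp, float),
                                      "YFP": np.asarray(yfp, float)},
                            stim_onset_s=onset)

    def test_constant_channels_zero(self):
        out = delta_r_over_r(self._fret(np.full(300, 60.0), np.full(300, 90.0)))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_anticorrelated_ten_percent_step_gives_22_2(self):
        cfp = np.concatenate([np.full(150, 100.0), np.full(150, 90.0)])
        yfp = np.concatenate([np.full(150, 100.0), np.full(150, 110.0)])
        out = delta_r_over_r(self._fret(cfp, yfp))
        assert out[-1] == pytest.approx((1.1 / 0.9 - 1) * 100, rel=1e-9)

    def test_channel_swap_inverts_step_direction(self):
        cfp = np.concatenate([np.full(150, 100.0), np.full(150, 90.0)])
        yfp = np.concatenate([np.full(150, 100.0), np.full(150, 110.0)])
        tr = self._fret(cfp, yfp)
        up = delta_r_over_r(tr, "yfp/cfp")
        down = delta_r_over_r(tr, "cfp/yfp")
        assert up[-1] > 0 > down[-1]

    def test_generator_step_matches_closed_form(self):
        tr = simulate_calcium_fret(10.0, -10.0, kernel="step")
        out = delta_r_over_r(tr)
        assert np.nanmax(out) == pytest.approx((1.1 / 0.9 - 1) * 100, rel=1e-9)


class TestNormalizeResponses:
    def _table(self):
        return pd.DataFrame({
            "concentration_M": [1e-9, 1e-8, 1e-7, 1e-6],
            "replicate": [0, 0, 0, 0],
            "ligand_lum": [0.0, 1e5, 4e5, 6e5],
            "lysis_lum": [1e6, 1e6, 1e6, 1e6],
        })

    def test_series_maximum_is_100_percent(self):
        out = normalize_responses(self._table())
        assert out["percent_activation"].max() == pytest.approx(100.0)

    def test_zero_ligand_gives_zero_percent(self):
        out = normalize_responses(self._table())
        assert out["percent_activation"].iloc[0] == 0.0

    def test_dead_well_excluded_with_warning(self):
        df = self._table()
        df.loc[1, ["ligand_lum", "lysis_lum"]] = 0.0
        with pytest.warns(UserWarning, match="zero total"):
            out = normalize_responses(df)
        assert len(out) == 3

    def test_empty_vector_control_stays_near_zero(self):
        # a non-responding series shows tiny percent activation everywhere
        # when scaled against a responding series' normalized values
        responder = simulate_dose_response(
            {"bottom": 0.02, "top": 0.6, "log_ec50": -7.5, "hill": 1.0},
            n_replicates=2, noise_sd=0.0, seed=0,
        )
        control = simulate_dose_response(
            {"bottom": 0.02, "top": 0.02, "log_ec50": -7.5, "hill": 1.0},
            n_replicates=2, noise_sd=0.0, seed=1,
        )
        resp = normalize_responses(responder)["normalized"].max()
        ctrl = normalize_responses(control)["normalized"].max()
        assert ctrl / resp < 0.05

    def test_replicate_summary_has_sem(self):
        df = simulate_dose_response(
            {"bottom": 0.05, "top": 0.5, "log_ec50": -7.0, "hill": 1.0},
            n_replicates=3, noise_sd=0.01, seed=3,
        )
        out = summarize_responses(normalize_responses(df))
        assert (out["n"] == 3).all()
        assert out["percent_activation_sem"].notna().all()


class TestFitDoseResponse:
    GEN = {"bottom": 0.03, "top": 0.55, "log_ec50": -7.2, "hill": 1.3}

    def test_noiseless_recovery_to_1e6_relative(self):
        conc = np.logspace(-10, -4, 8)
        df = simulate_dose_response(self.GEN, concentrations=conc, n_replicates=1)
        fit = fit_dose_response(normalize_responses(df))
        assert not fit.flagged
        for k, v in self.GEN.items():
            assert getattr(fit, k) == pytest.approx(v, rel=1e-6)
        assert fit.ec50 == pytest.approx(10 ** self.GEN["log_ec50"], rel=1e-6)

    def test_curve_at_ec50_is_midpoint(self):
        df = simulate_dose_response(self.GEN, n_replicates=1)
        fit = fit_dose_response(normalize_responses(df))
        mid = fit.predict(fit.ec50)
        assert mid == pytest.approx((fit.top + fit.bottom) / 2, rel=1e-9)

    def test_constant_data_flagged(self):
        df = pd.DataFrame({
            "concentration_M": np.logspace(-9, -5, 5),
            "ligand_lum": np.full(5, 2e5),
            "lysis_lum": np.full(5, 1e6),
        })
        fit = fit_dose_response(normalize_responses(df))
        assert fit.flagged and "constant" in fit.message

    def test_too_few_concentrations_rejected(self):
        df = pd.DataFrame({
            "concentration_M": [1e-8, 1e-7, 1e-6],
            "ligand_lum": [1e4, 1e5, 3e5],
            "lysis_lum": [1e6] * 3,
        })
        with pytest.raises(ValueError, match="4 distinct"):
            fit_dose_response(normalize_responses(df))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(0.01, 1000.0))
    def test_concentration_unit_rescaling_shifts_log_ec50(self, scale):
        conc = np.logspace(-10, -4, 8)
        df = simulate_dose_response(self.GEN, concentrations=conc, n_replicates=1)
        df = normalize_responses(df)
        base = fit_dose_response(df)
        scaled = df.assign(concentration_M=df["concentration_M"] * scale)
        refit = fit_dose_response(scaled)
        assert refit.log_ec50 == pytest.approx(base.log_ec50 + np.log10(scale), abs=1e-6)
        assert refit.ec50 == pytest.approx(base.ec50 * scale, rel=1e-5)

    def test_noisy_ec50_within_two_se_most_of_the_time(self):
        # smaller sweep here; the full 200-seed coverage runs in acceptance
        gen = {"bottom": 0.02, "top": 0.6, "log_ec50": -8.2, "hill": 1.0}
        hits = 0
        n = 40
        for seed in range(n):
            df = simulate_dose_response(gen, n_replicates=3, noise_sd=0.02, seed=seed)
            fit = fit_dose_response(normalize_responses(df))
            if abs(fit.log_ec50 - gen["log_ec50"]) <= 2 * fit.se["log_ec50"]:
                hits += 1
        assert hits / n >= 0.9
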