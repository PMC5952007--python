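"""PAC estimators, comodulograms, sliding-window trajectories, band power."""

import cmath

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pacbci.core import CANONICAL_BANDS, ValidationError, band_by_name
from pacbci.cfc import (analytic, comodulogram, iplv, mvl, pac, pac_phases,
                        pac_timeseries, plv, relative_power, signal_power,
                        surrogate_threshold)
from pacbci.synthetic import CouplingSpec, gen_coupled_signal

DELTA, THETA = CANONICAL_BANDS[0], CANONICAL_BANDS[1]

phase_lists = st.lists(
    st.floats(-np.pi, np.pi, allow_nan=False), min_size=1, max_size=6)


class TestAnalytic:
    def test_pure_cosine_amplitude_and_frequency(self):
        fs, dur, f = 250.0, 4.0, 6.0
        t = np.arange(int(fs * dur)) / fs
        a = analytic(np.cos(2 * np.pi * f * t))
        interior = slice(100, -100)
        assert np.all(np.abs(a.amplitude[interior] - 1.0) < 0.02)
        inst_f = np.diff(np.unwrap(a.phase[interior])) * fs / (2 * np.pi)
        assert abs(np.mean(inst_f) - f) < 0.05

    def test_scaling_linearity(self):
        x = np.cos(np.linspace(0, 20 * np.pi, 500))
        a1, a2 = analytic(x), analytic(2 * x)
        np.testing.assert_allclose(a2.amplitude, 2 * a1.amplitude, rtol=1e-12)

    def test_zero_input(self):
        a = analytic(np.zeros(64))
        np.testing.assert_array_equal(a.amplitude, 0.0)

    def test_nonfinite_rejected(self):
        x = np.zeros(64)
        x[10] = np.nan
        with pytest.raises(ValidationError):
            analytic(x)


class TestEstimatorIdentities:
    def test_plv_identical_phases_is_one(self, rng):
        phi = rng.uniform(-np.pi, np.pi, 200)
        assert plv(phi, phi) == pytest.approx(1.0)

    def test_plv_constant_offset_is_one(self, rng):
        phi = rng.uniform(-np.pi, np.pi, 200)
        for c in (0.3, -1.2, 2.9):
            assert plv(phi, phi + c) == pytest.approx(1.0)

    def test_iplv_zero_lag_is_zero(self, rng):
        phi = rng.uniform(-np.pi, np.pi, 200)
        assert iplv(phi, phi) == pytest.approx(0.0, abs=1e-12)

    def test_iplv_quarter_cycle_lag_is_one(self, rng):
        phi = rng.uniform(-np.pi, np.pi, 200)
        assert iplv(phi, phi - np.pi / 2) == pytest.approx(1.0)

    def test_independent_phases_scale_as_inverse_sqrt_t(self):
        # Monte Carlo: for T=1e4 the resultant is O(T^-1/2) ~ 0.01
        rng = np.random.default_rng(77)
        vals = [plv(rng.uniform(-np.pi, np.pi, 10_000),
                    rng.uniform(-np.pi, np.pi, 10_000)) for _ in range(200)]
        assert np.mean(np.array(vals) < 0.05) > 0.99

    def test_mvl_uniform_phasors_cancel(self):
        phi = np.linspace(-np.pi, np.pi, 720, endpoint=False)
        assert mvl(np.ones_like(phi), phi) == pytest.approx(0.0, abs=1e-9)

    def test_mvl_closed_form_half(self):
        phi = np.linspace(-np.pi, np.pi, 720, endpoint=False)
        assert mvl(1 + np.cos(phi), phi) == pytest.approx(0.5, abs=1e-9)

    def test_mvl_amplitude_linearity(self, rng):
        phi = rng.uniform(-np.pi, np.pi, 100)
        a = rng.uniform(0, 2, 100)
        assert mvl(2 * a, phi) == pytest.approx(2 * mvl(a, phi), rel=1e-12)

    def test_mvl_negative_amplitude_rejected(self):
        with pytest.raises(ValidationError):
            mvl(np.array([-1.0, 1.0]), np.array([0.0, 0.0]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            plv(np.zeros(3), np.zeros(4))


class TestEstimatorProperties:
    @settings(max_examples=60, derandomize=True)
    @given(phase_lists, phase_lists)
    def test_iplv_never_exceeds_plv(self, p1, p2):
        n = min(len(p1), len(p2))
        a, b = np.array(p1[:n]), np.array(p2[:n])
        assert iplv(a, b) <= plv(a, b) + 1e-12

    @settings(max_examples=40, derandomize=True)
    @given(phase_lists, st.floats(-np.pi, np.pi, allow_nan=False))
    def test_common_rotation_invariance(self, p, c):
        a = np.array(p)
        b = a[::-1].copy()
        assert plv(a + c, b + c) == pytest.approx(plv(a, b), abs=1e-12)
        assert iplv(a + c, b + c) == pytest.approx(iplv(a, b), abs=1e-12)

    @settings(max_examples=40, derandomize=True)
    @given(phase_lists)
    def test_brute_force_complex_arithmetic_oracle(self, p):
        """Direct cmath evaluation on short phase lists, 1e-12 agreement."""
        a = np.array(p)
        b = np.array([(-1) ** k * x for k, x in enumerate(p)])
        zsum = sum(cmath.exp(1j * (x - y)) for x, y in zip(a, b))
        assert plv(a, b) == pytest.approx(abs(zsum) / len(p), abs=1e-12)
        assert iplv(a, b) == pytest.approx(abs(zsum.imag) / len(p), abs=1e-12)
        amp = np.abs(a) + 0.5
        msum = sum(w * cmath.exp(1j * x) for w, x in zip(amp, a))
        assert mvl(amp, a) == pytest.approx(abs(msum) / len(p), abs=1e-12)

    def test_amplitude_scaling_leaves_phase_metrics_unchanged(self):
        x = gen_coupled_signal(CouplingSpec(depth=0.7), 250.0, 4.0, 0.3, 3)
        v1 = pac(x, DELTA, THETA, 250.0, "iplv").value
        v2 = pac(10.0 * x, DELTA, THETA, 250.0, "iplv").value
        assert v2 == pytest.approx(v1, rel=1e-9)


class TestPacChain:
    def test_phases_locked_by_construction(self):
        fs = 250.0
        x = gen_coupled_signal(CouplingSpec(2.0, 6.0, 1.0), fs, 8.0)
        phi_lf, phi_env, _ = pac_phases(x, DELTA, THETA, fs)
        # circular correlation of the two phase series
        z = np.mean(np.exp(1j * (phi_lf - phi_env)))
        assert abs(z) > 0.9

    def test_band_overlap_rejected(self):
        with pytest.raises(ValidationError):
            pac_phases(np.zeros(512), THETA, THETA, 250.0)

    def test_gap_between_bands_accepted(self):
        x = gen_coupled_signal(CouplingSpec(2.0, 9.0), 250.0, 4.0)
        pac_phases(x, DELTA, band_by_name("alpha1"), 250.0)

    def test_method_case_insensitive(self):
        x = gen_coupled_signal(CouplingSpec(), 250.0, 2.0)
        assert pac(x, DELTA, THETA, 250.0, "IPLV").method == "iplv"

    def test_unknown_method_rejected(self):
        x = gen_coupled_signal(CouplingSpec(), 250.0, 2.0)
        with pytest.raises(ValidationError):
            pac(x, DELTA, THETA, 250.0, "bicoherence")

    def test_depth_monotone_same_noise(self):
        fs = 250.0
        lo = pac(gen_coupled_signal(CouplingSpec(depth=0.2), fs, 4.0, 0.3, 9),
                 DELTA, THETA, fs, "iplv").value
        hi = pac(gen_coupled_signal(CouplingSpec(depth=0.8), fs, 4.0, 0.3, 9),
                 DELTA, THETA, fs, "iplv").value
        assert hi > lo

    def test_no_modulation_below_surrogate_null(self):
        fs = 250.0
        x = gen_coupled_signal(CouplingSpec(depth=0.0), fs, 6.0, 0.5, 4)
        phi_lf, phi_env, a_hf = pac_phases(x, DELTA, THETA, fs)
        thr = surrogate_threshold(phi_lf, phi_env, a_hf, "iplv", fs,
                                  n_surrogates=200, seed=0)
        assert iplv(phi_lf, phi_env) < thr


class TestComodulogram:
    def test_canonical_seven_gives_21_pairs(self):
        x = gen_coupled_signal(CouplingSpec(), 250.0, 2.0, 0.1, 0)
        com = comodulogram(x, CANONICAL_BANDS, 250.0, "iplv")
        assert com.n_pairs == 21
        assert np.sum(np.isfinite(com.values)) == 21

    def test_two_bands_give_one_pair(self):
        x = gen_coupled_signal(CouplingSpec(), 250.0, 2.0, 0.1, 0)
        com = comodulogram(x, [DELTA, THETA], 250.0, "plv")
        assert com.n_pairs == 1

    def test_injected_pair_is_argmax(self):
        x = gen_coupled_signal(CouplingSpec(2.0, 6.0, 0.9), 250.0, 4.0,
                               0.3, 11)
        com = comodulogram(x, CANONICAL_BANDS, 250.0, "iplv")
        lf, hf = com.argmax_pair()
        assert (lf.name, hf.name) == ("delta", "theta")

    def test_overlapping_bands_rejected(self):
        from pacbci.core import BandSpec
        with pytest.raises(ValidationError):
            comodulogram(np.zeros(512), [BandSpec("a", 1, 5),
                                         BandSpec("b", 4, 9)], 250.0)

    def test_matches_single_pair_pac(self):
        x = gen_coupled_signal(CouplingSpec(), 250.0, 3.0, 0.2, 5)
        com = comodulogram(x, CANONICAL_BANDS, 250.0, "iplv")
        direct = pac(x, DELTA, THETA, 250.0, "iplv").value
        assert com.values[0, 1] == pytest.approx(direct, rel=1e-9)


class TestPacTimeSeries:
    def test_length_formula(self):
        x = gen_coupled_signal(CouplingSpec(), 250.0, 5.252, 0.1, 0)
        assert x.size == 1313
        ts = pac_timeseries(x, DELTA, THETA, 250.0, window=25, step=1)
        assert len(ts.values) == 1289  # floor((1313-25)/1)+1

    def test_window_equals_signal(self):
        x = gen_coupled_signal(CouplingSpec(), 250.0, 2.0)
        ts = pac_timeseries(x, DELTA, THETA, 250.0, window=x.size)
        assert len(ts.values) == 1

    def test_target_length_centred_truncation(self):
        x = gen_coupled_signal(CouplingSpec(), 250.0, 4.0, 0.1, 1)
        full = pac_timeseries(x, DELTA, THETA, 250.0, 25, 1)
        cut = pac_timeseries(x, DELTA, THETA, 250.0, 25, 1,
                             target_length=501)
        lo = (len(full.values) - 501) // 2
        np.testing.assert_array_equal(cut.values,
                                      full.values[lo:lo + 501])

    def test_stationary_coupling_low_variation(self):
        x = gen_coupled_signal(CouplingSpec(depth=1.0), 250.0, 6.0, 0.1, 2)
        ts = pac_timeseries(x, DELTA, THETA, 250.0, window=50, step=5)
        assert ts.values.std() / ts.values.mean() < 0.5

    def test_window_too_large_rejected(self):
        with pytest.raises(ValidationError):
            pac_timeseries(np.zeros(100), DELTA, THETA, 250.0, window=200)


class TestBandPower:
    def test_signal_power_examples(self):
        assert signal_power(np.ones(100)) == 100.0
        assert signal_power(np.zeros(50)) == 0.0

    def test_sinusoid_power_analytic(self):
        fs, dur, a = 250.0, 4.0, 3.0
        t = np.arange(int(fs * dur)) / fs
        x = a * np.cos(2 * np.pi * 5.0 * t)
        assert signal_power(x) == pytest.approx(a ** 2 * x.size / 2, rel=1e-3)

    def test_pure_alpha_tone_dominates_alpha1(self):
        # long signal so the narrow-band filter transients are negligible
        fs = 512.0
        t = np.arange(int(16 * fs)) / fs
        prof = relative_power(np.cos(2 * np.pi * 9.0 * t),
                              CANONICAL_BANDS, fs)
        assert prof.rsp[2] > 0.9

    def test_rsp_sums_to_one(self, rng):
        prof = relative_power(rng.standard_normal(1024),
                              CANONICAL_BANDS, 512.0)
        assert prof.rsp.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(prof.rsp >= 0)

    def test_all_zero_signal_rejected(self):
        with pytest.raises(ValidationError):
            relative_power(np.zeros(1024), CANONICAL_BANDS, 512.0)

    def test_fewer_than_two_bands_rejected(self):
        with pytest.raises(ValidationError):
            relative_power(np.ones(256), [DELTA], 512.0)
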