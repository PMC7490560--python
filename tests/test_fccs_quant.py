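"""Analytic correlation models, correlator, fitting and K_d estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nrf2net.fccs_quant import (
    CellMeasurement,
    CorrelationCurve,
    CorrelationNormalizationError,
    DiffusionFitParams,
    amplitudes_to_concentrations,
    concentrations_to_amplitudes,
    eval_autocorr_model,
    eval_crosscorr_model,
    fit_correlation_curve,
    fit_kd_isotherm,
    multitau_correlate,
    qc_cell,
)
from nrf2net.synthetic_data import solve_equilibrium


# ---------------------------------------------------------------------------
# Analytic models
# ---------------------------------------------------------------------------


class TestCorrelationModels:
    def test_zero_lag_amplitude_is_inverse_particle_number(self, volume):
        p = DiffusionFitParams(n_particles=10.0, triplet_fraction=0.0)
        g = eval_autocorr_model(np.array([0.0]), p, volume)
        assert g[0] == pytest.approx(0.1, rel=1e-12)

    def test_decorrelation_limit_is_offset(self, volume):
        p = DiffusionFitParams(n_particles=5.0, offset=0.007)
        g = eval_autocorr_model(np.array([1e9]), p, volume)
        assert g[0] == pytest.approx(0.007, abs=1e-9)

    def test_single_component_value_at_tau_d(self, volume):
        # N=10, f_fast=1, tau = tau_D, s=5, T=0: G = 0.05 * 1.04^-0.5
        p = DiffusionFitParams(n_particles=10.0, f_fast=1.0, tau_d_fast=1e-3,
                               tau_d_slow=1e-3, triplet_fraction=0.0)
        g = eval_autocorr_model(np.array([1e-3]), p, volume)
        assert g[0] == pytest.approx(0.05 * 1.04**-0.5, rel=1e-12)
        assert g[0] == pytest.approx(0.049029, abs=1e-6)

    def test_cross_equals_auto_without_triplet(self, volume):
        lags = np.geomspace(1e-6, 1.0, 50)
        p = DiffusionFitParams(n_particles=3.0, f_fast=0.5, tau_d_fast=1e-4,
                               tau_d_slow=1e-2, triplet_fraction=0.0)
        np.testing.assert_array_equal(
            eval_crosscorr_model(lags, p, volume), eval_autocorr_model(lags, p, volume)
        )
        # and the cross model ignores any triplet fraction on the params
        p_trip = DiffusionFitParams(n_particles=3.0, f_fast=0.5, tau_d_fast=1e-4,
                                    tau_d_slow=1e-2, triplet_fraction=0.3)
        np.testing.assert_array_equal(
            eval_crosscorr_model(lags, p_trip, volume),
            eval_autocorr_model(lags, p, volume),
        )

    @settings(max_examples=50, derandomize=True)
    @given(
        n=st.floats(min_value=0.5, max_value=1e3),
        f=st.floats(min_value=0.0, max_value=1.0),
        t_frac=st.floats(min_value=0.0, max_value=0.6),
    )
    def test_model_monotone_decay(self, volume, n, f, t_frac):
        """With offset 0 the model decays monotonically in lag time."""
        lags = np.geomspace(1e-7, 10.0, 200)
        p = DiffusionFitParams(n_particles=n, f_fast=f, tau_d_fast=2e-4,
                               tau_d_slow=8e-3, triplet_fraction=t_frac)
        g = eval_autocorr_model(lags, p, volume)
        assert np.all(np.diff(g) <= 1e-15)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DiffusionFitParams(n_particles=10.0, triplet_fraction=1.0)
        with pytest.raises(ValueError):
            DiffusionFitParams(n_particles=10.0, tau_d_fast=1e-2, tau_d_slow=1e-3)
        with pytest.raises(ValueError):
            DiffusionFitParams(n_particles=-1.0)


# ---------------------------------------------------------------------------
# Multi-tau correlator
# ---------------------------------------------------------------------------


def brute_force_correlator(a, b, lags):
    """Independent O(N^2)-style oracle: explicit per-lag products."""
    ma, mb = np.mean(a), np.mean(b)
    out = []
    for k in lags:
        s = 0.0
        for t in range(len(a) - k):
            s += (a[t] - ma) * (b[t + k] - mb)
        out.append(s / ((len(a) - k) * ma * mb))
    return np.array(out)


class TestMultitauCorrelator:
    def test_constant_trace_gives_zero(self):
        curve = multitau_correlate(np.full(256, 7.0))
        np.testing.assert_array_equal(curve.g, 0.0)

    def test_auto_is_cross_with_itself(self, rng):
        a = rng.poisson(4.0, 512).astype(float)
        auto = multitau_correlate(a)
        cross = multitau_correlate(a, a)
        np.testing.assert_array_equal(auto.g, cross.g)

    def test_matches_brute_force_oracle(self, rng):
        a = rng.poisson(5.0, 1024).astype(float)
        b = a + rng.poisson(2.0, 1024)  # correlated traces
        curve = multitau_correlate(a, b)
        lags = curve.lags.astype(int)
        expected = brute_force_correlator(a, b, lags)
        np.testing.assert_allclose(curve.g, expected, atol=1e-12)

    def test_zero_mean_trace_raises(self):
        with pytest.raises(CorrelationNormalizationError):
            multitau_correlate(np.zeros(128))

    def test_lag_ladder_log_spaced_and_dt_scaled(self, rng):
        a = rng.poisson(3.0, 2048).astype(float)
        curve = multitau_correlate(a, dt=1e-5)
        assert np.all(np.diff(curve.lags) > 0)
        steps = np.diff(curve.lags.astype(float))
        assert steps[-1] > steps[0]  # coarsening schedule
        assert curve.lags[0] == pytest.approx(1e-5)


# ---------------------------------------------------------------------------
# Curve fitting
# ---------------------------------------------------------------------------


def _make_curve(params, volume, model="auto", n_lags=160, sem=0.0):
    lags = np.geomspace(1e-6, 1.0, n_lags)
    ev = eval_autocorr_model if model == "auto" else eval_crosscorr_model
    g = ev(lags, params, volume)
    channel = "green_auto" if model == "auto" else "cross"
    return CorrelationCurve(channel, lags, g, np.full_like(g, sem))


class TestCurveFitting:
    def test_noise_free_round_trip(self, volume):
        truth = DiffusionFitParams(n_particles=20.0, f_fast=0.7, tau_d_fast=5e-4,
                                   tau_d_slow=5e-3, triplet_fraction=0.15)
        fit = fit_correlation_curve(_make_curve(truth, volume), "auto", volume=volume)
        for name in ("n_particles", "f_fast", "tau_d_fast", "tau_d_slow",
                     "triplet_fraction", "tau_triplet"):
            assert getattr(fit, name) == pytest.approx(getattr(truth, name), rel=1e-4)
        assert fit.converged

    def test_sem_zero_means_unweighted_same_recovery(self, volume):
        truth = DiffusionFitParams(n_particles=3.0, f_fast=0.5, tau_d_fast=2e-4,
                                   tau_d_slow=4e-3, triplet_fraction=0.0)
        fit = fit_correlation_curve(_make_curve(truth, volume, "cross"), "cross",
                                    volume=volume)
        assert fit.n_particles == pytest.approx(3.0, rel=1e-4)
        assert fit.triplet_fraction == 0.0

    def test_noisy_recovery_within_tolerance(self, volume, rng):
        truth = DiffusionFitParams(n_particles=15.0, f_fast=1.0, tau_d_fast=1e-3,
                                   tau_d_slow=1e-3, triplet_fraction=0.1)
        curve = _make_curve(truth, volume)
        noise_sd = 0.02 * truth.g0 / np.sqrt(1.0 + curve.lags / 1e-3)
        curve.g = curve.g + rng.normal(0, 1, curve.g.shape) * noise_sd
        curve.sem = noise_sd
        fit = fit_correlation_curve(curve, "auto", volume=volume)
        assert fit.n_particles == pytest.approx(15.0, rel=0.05)
        tau_eff = fit.f_fast * fit.tau_d_fast + fit.f_slow * fit.tau_d_slow
        assert tau_eff == pytest.approx(1e-3, rel=0.10)

    def test_too_few_lags_rejected(self, volume):
        truth = DiffusionFitParams(n_particles=5.0)
        with pytest.raises(ValueError, match="lags"):
            fit_correlation_curve(_make_curve(truth, volume, n_lags=20), "auto",
                                  volume=volume)


# ---------------------------------------------------------------------------
# Amplitude -> concentration conversion
# ---------------------------------------------------------------------------


class TestAmplitudeConversion:
    def test_no_codiffusion(self, volume):
        m = amplitudes_to_concentrations(0.1, 0.1, 0.0, volume)
        assert m.c_complex == 0.0
        assert m.f_bound_green == 0.0 and m.f_bound_red == 0.0

    def test_full_codiffusion(self, volume):
        m = amplitudes_to_concentrations(0.05, 0.05, 0.05, volume)
        assert m.f_bound_green == pytest.approx(1.0)
        assert m.f_bound_red == pytest.approx(1.0)

    def test_avogadro_arithmetic(self):
        from nrf2net.fccs_quant import ConfocalVolume

        one_fl = ConfocalVolume(v_eff_fL=1.0, s=5.0)
        m = amplitudes_to_concentrations(1.0, 1.0, 0.0, one_fl)
        assert m.c_g_total == pytest.approx(1.6605, abs=1e-3)  # 1/(1e-15 L * N_A) in nM

    def test_inconsistent_amplitudes_flagged(self, volume):
        # cross amplitude implying more complex than the limiting total
        m = amplitudes_to_concentrations(0.1, 0.01, 0.5, volume)
        assert "inconsistent" in m.flags
        assert m.c_complex <= min(m.c_g_total, m.c_r_total)
        assert m.c_g_free + m.c_complex == pytest.approx(m.c_g_total, rel=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(
        cg=st.floats(min_value=1.0, max_value=1e4),
        cr=st.floats(min_value=1.0, max_value=1e4),
        frac=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_round_trip_identity(self, volume, cg, cr, frac):
        """concentrations -> amplitudes -> concentrations is the identity."""
        cc = frac * min(cg, cr)
        g0g, g0r, g0x = concentrations_to_amplitudes(cg, cr, cc, volume)
        m = amplitudes_to_concentrations(g0g, g0r, g0x, volume)
        assert m.c_g_total == pytest.approx(cg, rel=1e-9)
        assert m.c_r_total == pytest.approx(cr, rel=1e-9)
        assert m.c_complex == pytest.approx(cc, rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def _measurement(**kw):
    base = dict(g0_green=0.1, g0_red=0.1, g0_cross=0.02, c_g_total=50.0,
                c_r_total=50.0, c_complex=10.0, c_g_free=40.0, c_r_free=40.0,
                f_bound_green=0.2, f_bound_red=0.2)
    base.update(kw)
    return CellMeasurement(**base)


class TestQc:
    def test_good_cell_passes(self):
        curve = CorrelationCurve("green_auto", [1e-5, 1e-4], [0.1, 0.05], [0, 0],
                                 meta={"cpm_kHz": 1.0})
        res = qc_cell(_measurement(), [curve])
        assert res.passed and res.reasons == ()

    def test_negative_amplitude_fails_with_reason(self):
        res = qc_cell(_measurement(g0_green=-0.01))
        assert not res.passed
        assert "amplitude" in res.reasons

    def test_low_cpm_fails(self):
        curve = CorrelationCurve("green_auto", [1e-5, 1e-4], [0.1, 0.05], [0, 0],
                                 meta={"cpm_kHz": 0.2})
        assert not qc_cell(_measurement(), [curve]).passed

    def test_unconverged_fit_fails(self):
        bad = DiffusionFitParams(n_particles=1.0, converged=False)
        assert not qc_cell(_measurement(), fits={"green_auto": bad}).passed

    def test_injected_failures_are_counted_out(self):
        """40 cells, 5 with bad amplitudes: exactly 35 enter the isotherm."""
        cells = []
        state = solve_equilibrium(2000.0, 2000.0, 2000.0)
        for i in range(40):
            m = _measurement(
                c_g_free=state.c_g_free, c_r_free=state.c_r_free,
                f_bound_green=state.c_complex / state.c_g_total,
                f_bound_red=state.c_complex / state.c_r_total,
            )
            if i < 5:
                m = _measurement(g0_green=-1e-6)
            qc_cell(m)
            cells.append(m)
        fit = fit_kd_isotherm(cells, n_boot=50, seed=0)
        assert fit.n_cells == 35


# ---------------------------------------------------------------------------
# Binding isotherm
# ---------------------------------------------------------------------------


def _cells_on_isotherm(kd, c_free_values):
    cells = []
    for c in c_free_values:
        f = c / (c + kd)
        cells.append(_measurement(c_g_free=c, c_r_free=c, f_bound_green=f, f_bound_red=f))
    return cells


class TestKdIsotherm:
    def test_half_saturation_definition(self):
        """f_bound = 0.5 at c_free = 2000 nM pins K_d = 2000 nM."""
        cells = _cells_on_isotherm(2000.0, np.geomspace(100, 5e4, 12))
        fit = fit_kd_isotherm(cells, n_boot=50, seed=1)
        assert fit.kd_mean == pytest.approx(2000.0, rel=1e-4)
        assert fit.kd_green_orientation == pytest.approx(fit.kd_red_orientation, rel=1e-6)
        assert fit.binder_flag

    def test_non_binder_sentinel(self):
        cells = [_measurement(f_bound_green=0.0, f_bound_red=0.0) for _ in range(12)]
        fit = fit_kd_isotherm(cells, n_boot=20, seed=0)
        assert math.isinf(fit.kd_mean)
        assert not fit.binder_flag

    def test_binder_threshold(self):
        cells = _cells_on_isotherm(20000.0, np.geomspace(1e3, 3e5, 15))
        fit = fit_kd_isotherm(cells, n_boot=50, seed=2)
        assert fit.kd_mean == pytest.approx(20000.0, rel=1e-3)
        assert not fit.binder_flag  # above the 10,000 nM positive-binder threshold

    def test_orientation_relabelling_invariance(self):
        """Swapping channels (green<->red) symmetrically swaps the two
        orientation estimates but leaves the mean K_d unchanged."""
        rng = np.random.default_rng(7)
        cells, swapped = [], []
        for _ in range(20):
            cg, cr = 10 ** rng.uniform(2, 4, 2)
            st_ = solve_equilibrium(cg, cr, 1500.0)
            kw = dict(
                c_g_free=st_.c_g_free, c_r_free=st_.c_r_free,
                f_bound_green=st_.c_complex / st_.c_g_total,
                f_bound_red=st_.c_complex / st_.c_r_total,
            )
            cells.append(_measurement(**kw))
            swapped.append(_measurement(
                c_g_free=kw["c_r_free"], c_r_free=kw["c_g_free"],
                f_bound_green=kw["f_bound_red"], f_bound_red=kw["f_bound_green"],
            ))
        fit = fit_kd_isotherm(cells, n_boot=10, seed=3)
        fit_sw = fit_kd_isotherm(swapped, n_boot=10, seed=3)
        assert fit.kd_green_orientation == pytest.approx(fit_sw.kd_red_orientation, rel=1e-9)
        assert fit.kd_mean == pytest.approx(fit_sw.kd_mean, rel=1e-9)

    def test_bootstrap_ci_shrinks_with_n(self):
        rng = np.random.default_rng(11)

        def width(n_cells, seed):
            cells = []
            for _ in range(n_cells):
                cg, cr = 10 ** rng.uniform(2.0, 3.5, 2)
                st_ = solve_equilibrium(cg, cr, 1000.0)
                f_g = st_.c_complex / st_.c_g_total + rng.normal(0, 0.03)
                f_r = st_.c_complex / st_.c_r_total + rng.normal(0, 0.03)
                cells.append(_measurement(
                    c_g_free=st_.c_g_free, c_r_free=st_.c_r_free,
                    f_bound_green=float(np.clip(f_g, 0, 1)),
                    f_bound_red=float(np.clip(f_r, 0, 1)),
                ))
            fit = fit_kd_isotherm(cells, n_boot=200, seed=seed)
            return fit.ci95[1] - fit.ci95[0]

        small = np.mean([width(15, s) for s in range(4)])
        large = np.mean([width(120, s) for s in range(4)])
        assert large < small

    def test_requires_enough_cells(self):
        with pytest.raises(ValueError, match="qc-passing"):
            fit_kd_isotherm(_cells_on_isotherm(1000.0, [100.0] * 5))
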