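"""Cycle segmentation and Lissajous feature extraction against closed forms."""

import numpy as np
import pytest

import fibrheo as fr
from fibrheo.features import (
    SQRT2_HALF,
    SAOSRecord,
    estimate_G0,
    extract_moduli,
    extract_nsp,
    extract_stiffening,
    saos_to_series,
    segment_cycles,
    stresses_at_fractions,
)
from fibrheo.protocol import ProtocolSegment, StrainProtocol
from fibrheo.simulate import StressTimeSeries, simulate


def make_ellipse(G, eta, gamma0, f=1.0, n_cycles=1, n_per=1000):
    """Analytic linear Kelvin-Voigt loop (exact ellipse)."""
    t = np.arange(n_cycles * n_per) / (f * n_per)
    om = 2.0 * np.pi * f
    g = gamma0 * np.sin(om * t)
    gd = gamma0 * om * np.cos(om * t)
    return StressTimeSeries(t=t, gamma=g, gamma_dot=gd, tau=G * g + eta * gd)


class TestSegmentCycles:
    def test_sixty_seconds_at_one_hertz(self, truth):
        proto = StrainProtocol(segments=(ProtocolSegment(0.5, 1.0, 60.0),))
        s = simulate(proto, truth)
        assert len(segment_cycles(s, proto)) == 60

    def test_shorter_than_one_period_is_empty(self, truth):
        proto = StrainProtocol(segments=(ProtocolSegment(0.5, 1.0, 60.0),))
        s = simulate(proto, truth)
        short = StressTimeSeries(
            t=s.t[:800], gamma=s.gamma[:800], gamma_dot=s.gamma_dot[:800],
            tau=s.tau[:800],
        )
        assert segment_cycles(short, proto) == []

    def test_each_range_spans_one_period(self, truth):
        proto = StrainProtocol(segments=(ProtocolSegment(0.3, 1.0, 10.0),))
        s = simulate(proto, truth)
        spans = segment_cycles(s, proto)
        assert len(spans) == 10
        dt = s.t[1] - s.t[0]
        for sp in spans:
            assert s.t[sp.stop] - s.t[sp.start] == pytest.approx(1.0, abs=1.5 * dt)

    def test_full_ladder_count(self, ladder_series, ladder):
        assert len(segment_cycles(ladder_series, ladder)) == 7 * 60


class TestEstimateG0:
    def test_pure_elastic_line(self):
        s = make_ellipse(5.0, 0.0, 0.5)
        assert estimate_G0(s.gamma, s.gamma_dot, s.tau, 0.5) == pytest.approx(
            5.0, rel=1e-6
        )

    def test_viscous_offset_cancels_on_ellipse(self):
        s = make_ellipse(10.0, 0.2, 0.5)
        G0 = estimate_G0(s.gamma, s.gamma_dot, s.tau, 0.5)
        assert G0 == pytest.approx(10.0, rel=1e-4)

    def test_amplitude_independent_on_linear_model(self, linear_params):
        vals = []
        for g0 in (0.25, 0.5, 1.0):
            proto = StrainProtocol(segments=(ProtocolSegment(g0, 1.0, 3.0),))
            s = simulate(proto, linear_params)
            feats = fr.extract_cycle_features(s, proto)
            vals.append(feats["G0"].iloc[-1])
        assert np.ptp(vals) / np.mean(vals) < 0.01

    def test_small_amplitude_uses_peak_secant(self):
        s = make_ellipse(7.0, 0.0, 0.01)
        assert estimate_G0(s.gamma, s.gamma_dot, s.tau, 0.01) == pytest.approx(
            7.0, rel=1e-4
        )

    def test_unreachable_window_flags_missing(self):
        s = make_ellipse(5.0, 0.1, 0.04)
        assert np.isnan(estimate_G0(s.gamma, s.gamma_dot, s.tau, 0.06))

    def test_bounded_by_window_stiffening(self, ladder_series, ladder, truth):
        """On the nonlinear model the window slope reads G00*x*f(window), so
        G0/(G00*x) must sit in [1, f(0.05)]."""
        feats = fr.extract_cycle_features(ladder_series, ladder)
        fmax = fr.stiffening_factor(0.05, truth.k1, truth.n1)
        big = feats[feats["gamma0"] >= 0.25]
        x_mid = np.interp(big["t_mid"], ladder_series.t, ladder_series.x)
        ratio = big["G0"].to_numpy() / (truth.G00 * x_mid)
        assert np.all(ratio > 0.995)
        assert np.all(ratio < fmax * 1.005)


class TestFractionStresses:
    def test_elastic_loop_has_no_hysteresis(self):
        s = make_ellipse(5.0, 0.0, 0.5)
        up_h, down_h, up_s, down_s = stresses_at_fractions(
            s.gamma, s.gamma_dot, s.tau, 0.5
        )
        assert up_h == pytest.approx(down_h, abs=1e-9)
        assert up_s == pytest.approx(down_s, abs=1e-9)

    @pytest.mark.parametrize("frac", [0.5, SQRT2_HALF])
    def test_ellipse_width_closed_form(self, frac):
        """On the linear ellipse tau_up - tau_down = 2*eta*omega*gamma0*
        cos(arcsin(frac))."""
        eta, gamma0, om = 0.2, 0.5, 2.0 * np.pi
        s = make_ellipse(10.0, eta, gamma0)
        vals = stresses_at_fractions(
            s.gamma, s.gamma_dot, s.tau, gamma0, fractions=(frac,)
        )
        width = vals[0] - vals[1]
        expected = 2.0 * eta * om * gamma0 * np.cos(np.arcsin(frac))
        assert width == pytest.approx(expected, rel=1e-3)

    def test_interpolation_matches_oversampled_loop(self, truth):
        proto = StrainProtocol(segments=(ProtocolSegment(1.0, 1.0, 3.0),))
        coarse = simulate(proto, truth, dt=1e-3)
        fine = simulate(proto, truth, dt=1e-4)
        fc = fr.extract_cycle_features(coarse, proto)
        ff = fr.extract_cycle_features(fine, proto)
        for col in ("tau_half_up", "tau_half_down", "tau_sqrt2_up", "tau_sqrt2_down"):
            err = np.abs(fc[col] - ff[col]) / ff["tau0"]
            assert err.max() < 0.005


class TestNSPAndStiffeningExtraction:
    def test_extract_nsp_proportionality(self):
        assert extract_nsp(8.0, 8.0) == pytest.approx(1.0)
        assert extract_nsp(4.0, 8.0) == pytest.approx(0.5)

    def test_extract_stiffening_linearity(self):
        f1 = extract_stiffening(10.0, 1.0, 0.5, 10.0)
        f2 = extract_stiffening(20.0, 1.0, 0.5, 10.0)
        assert f2 == pytest.approx(2.0 * f1)
        assert np.isnan(extract_stiffening(10.0, 1.0, 0.0, 10.0))

    def test_linear_model_has_unit_stiffening(self, linear_params):
        proto = StrainProtocol(
            segments=tuple(
                ProtocolSegment(a, 1.0, 5.0) for a in (0.1, 0.5, 1.0)
            )
        )
        s = simulate(proto, linear_params)
        feats = fr.extract_cycle_features(s, proto, G00=linear_params.G00)
        assert np.allclose(feats["f_e"], 1.0, atol=0.02)

    def test_round_trip_against_ground_truth(self, ladder_series, ladder, truth):
        """Noise-free simulate -> extract recovers the state and stiffening
        factor within a few percent at the larger amplitudes."""
        feats = fr.extract_cycle_features(ladder_series, ladder, G00=truth.G00)
        x_true = np.interp(feats["t_mid"], ladder_series.t, ladder_series.x)
        f_true = fr.stiffening_factor(
            feats["gamma0"].to_numpy(), truth.k1, truth.n1
        )
        big = feats["gamma0"].to_numpy() >= 0.25
        mid = (feats["gamma0"].to_numpy() >= 0.05) & ~big
        rel_x = np.abs(feats["x_e"] - x_true) / x_true
        rel_f = np.abs(feats["f_e"] - f_true) / f_true
        assert rel_x[big].max() < 0.02
        assert rel_f[big].max() < 0.03
        assert rel_x[mid].max() < 0.10

    def test_stiffening_value_at_unit_amplitude(self, truth):
        p = truth.replace(k1=3.0, n1=1.0)
        proto = fr.standard_laos_protocol()
        s = simulate(proto, p)
        feats = fr.extract_cycle_features(s, proto, G00=p.G00)
        last = feats[np.isclose(feats["gamma0"], 1.0, atol=1e-3)]["f_e"]
        assert last.iloc[-1] == pytest.approx(4.0, rel=0.03)


class TestSAOS:
    def test_phase_of_reconstruction(self):
        recs = [SAOSRecord(t=0.0, G_prime=5.0, G_double_prime=0.0,
                           amplitude=0.01, frequency=1.0)]
        s = saos_to_series(recs)
        assert np.allclose(s.tau, 5.0 * s.gamma)
        recs = [SAOSRecord(t=0.0, G_prime=0.0, G_double_prime=2.0,
                           amplitude=0.01, frequency=1.0)]
        s = saos_to_series(recs)
        om = 2.0 * np.pi
        assert np.allclose(s.tau, 2.0 * s.gamma_dot / om)

    def test_moduli_round_trip(self):
        recs = [
            SAOSRecord(t=float(i), G_prime=8.4, G_double_prime=0.628,
                       amplitude=0.01, frequency=1.0)
            for i in range(5)
        ]
        series = saos_to_series(recs, samples_per_cycle=200)
        proto = StrainProtocol(segments=(ProtocolSegment(0.01, 1.0, 5.0),),
                               sample_rate=200.0)
        back = extract_moduli(series, proto)
        assert len(back) == 5
        for r in back:
            assert r.G_prime == pytest.approx(8.4, rel=1e-3)
            assert r.G_double_prime == pytest.approx(0.628, rel=1e-3)

    def test_record_validation(self):
        with pytest.raises(ValueError):
            SAOSRecord(t=0.0, G_prime=-1.0, G_double_prime=0.0,
                       amplitude=0.01, frequency=1.0)
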