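"""Riccati scale dynamics: closed forms, identities, morphology and regimes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from exufiber import (
    HarmonicMapParams,
    Regime,
    RiccatiParams,
    classify_regime,
    harmonic_map_h,
    morphology_field,
    riccati_roots,
    riccati_solution,
    riccati_solution_real_form,
)
from exufiber.scale_model import (
    NonOscillatoryError,
    morphology_amplitude,
    regime_features,
)

from conftest import canonical_trace, random_oscillatory_params


class TestRoots:
    @pytest.mark.parametrize(
        "a1,a2,a3,tau0,omega",
        [
            (1.0, 0.0, 1.0, 1j, 1.0),
            (2.0, 1.0, 1.0, -0.5 + 0.5j, 1.0),
        ],
    )
    def test_known_roots(self, a1, a2, a3, tau0, omega):
        roots = riccati_roots(RiccatiParams(a1, a2, a3))
        assert roots.tau0 == pytest.approx(tau0, abs=1e-12)
        assert roots.tau0_conj == pytest.approx(tau0.conjugate(), abs=1e-12)
        assert roots.omega == pytest.approx(omega, rel=1e-12)

    def test_roots_satisfy_quadratic(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = random_oscillatory_params(rng)
            roots = riccati_roots(p)
            for z in (roots.tau0, roots.tau0_conj):
                assert abs(p.a1 * z**2 + 2 * p.a2 * z + p.a3) < 1e-10
            # cross-check against the independent polynomial-root oracle
            np_roots = np.roots([p.a1, 2 * p.a2, p.a3])
            assert sorted(np_roots, key=lambda c: c.imag) == pytest.approx(
                sorted([roots.tau0, roots.tau0_conj], key=lambda c: c.imag), abs=1e-9
            )
            assert roots.omega > 0

    def test_negative_discriminant_rejected(self):
        with pytest.raises(NonOscillatoryError):
            RiccatiParams(1.0, 2.0, 1.0)  # Omega**2 = -3

    def test_zero_a1_rejected(self):
        with pytest.raises(ValueError, match="a1"):
            RiccatiParams(0.0, 0.0, 1.0)

    def test_r_out_of_range_directs_to_hyperbolic_family(self):
        with pytest.raises(ValueError, match="harmonic_map_h"):
            RiccatiParams(1.0, 0.0, 1.0, r=1.2)


class TestClosedForm:
    def test_fixed_point_at_r_zero(self):
        p = RiccatiParams(1.0, 0.0, 1.0, r=0.0, tau_r=0.7)
        y = riccati_solution(p, np.linspace(-3, 3, 11))
        assert np.allclose(y, 1j, atol=1e-14)

    def test_values_at_phase_origin_and_quarter_period(self, unit_params):
        y = riccati_solution(unit_params, [0.0, np.pi / 4])
        assert y[0] == pytest.approx(1j / 3, abs=1e-14)
        assert y[1] == pytest.approx(0.8 + 0.6j, abs=1e-12)

    def test_real_form_agrees_pointwise(self):
        rng = np.random.default_rng(3)
        t = np.linspace(-2, 5, 257)
        for _ in range(10):
            p = random_oscillatory_params(rng)
            assert np.allclose(
                riccati_solution(p, t), riccati_solution_real_form(p, t), atol=1e-12
            )

    def test_real_part_at_phase_origin(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            p = random_oscillatory_params(rng)
            y = riccati_solution_real_form(p, p.tau_r)
            assert y.real == pytest.approx(-p.a2 / p.a1, abs=1e-12)

    def test_cross_ratio_modulus_conserved(self):
        rng = np.random.default_rng(5)
        t = np.linspace(0, 7, 101)
        for _ in range(10):
            p = random_oscillatory_params(rng)
            roots = riccati_roots(p)
            y = riccati_solution(p, t)
            mod = np.abs((y - roots.tau0) / (y - roots.tau0_conj))
            assert np.allclose(mod, p.r, atol=1e-10)

    def test_periodicity(self):
        rng = np.random.default_rng(6)
        t = np.linspace(0, 3, 37)
        for _ in range(10):
            p = random_oscillatory_params(rng)
            omega = riccati_roots(p).omega
            assert np.allclose(
                riccati_solution(p, t + np.pi / omega),
                riccati_solution(p, t),
                atol=1e-10,
            )

    def test_upper_half_plane_when_a1_positive(self):
        rng = np.random.default_rng(7)
        t = np.linspace(0, 10, 301)
        for _ in range(10):
            p = random_oscillatory_params(rng)
            assert np.all(riccati_solution(p, t).imag > 0)

    def test_ode_oracle_equivalence(self):
        """The closed form solves dy/dt = a1 y^2 + 2 a2 y + a3 (numeric oracle)."""
        rng = np.random.default_rng(42)
        t_eval = np.linspace(0, 5, 201)
        worst = 0.0
        for _ in range(20):
            p = random_oscillatory_params(rng)

            def rhs(t, u):
                y = u[0] + 1j * u[1]
                dy = p.a1 * y**2 + 2 * p.a2 * y + p.a3
                return [dy.real, dy.imag]

            y0 = riccati_solution(p, 0.0)
            sol = solve_ivp(rhs, (0, 5), [y0.real, y0.imag], t_eval=t_eval,
                            rtol=1e-10, atol=1e-12)
            assert sol.success
            y_num = sol.y[0] + 1j * sol.y[1]
            worst = max(worst, np.max(np.abs(y_num - riccati_solution(p, t_eval))))
        assert worst < 1e-6


class TestMorphologyField:
    def test_zero_modulus_gives_zero_field(self):
        fld = morphology_field(np.linspace(0.1, 1, 5), np.linspace(0, 10, 50), r=0.0)
        assert np.all(fld.values == 0)

    def test_odd_symmetry_about_phase_origin(self):
        tau_r = 1.3
        fld = morphology_field(np.linspace(0.2, 2, 7), np.array([tau_r]), r=0.4, tau_r=tau_r)
        assert np.allclose(fld.values, 0.0, atol=1e-12)

    def test_known_value_and_peak(self):
        fld = morphology_field(np.array([1.0]), np.array([np.pi / 4]), r=0.5)
        assert fld.values[0, 0] == pytest.approx(0.8, abs=1e-12)
        assert morphology_amplitude(0.5, 1.0) == pytest.approx(4 / 3, rel=1e-12)

    @pytest.mark.parametrize("r", [0.1, 0.5, 0.9])
    @pytest.mark.parametrize("omega", [0.5, 1.0, 10.0])
    def test_peak_law(self, r, omega):
        period = np.pi / omega
        t = np.linspace(0, period, 3000, endpoint=False)
        fld = morphology_field(np.array([omega]), t, r)
        peak = np.abs(fld.values[0]).max()
        assert peak == pytest.approx(2 * r * omega / (1 - r**2), rel=1e-3)

    def test_field_matches_re_a1z_plus_a2_of_solution(self):
        """Field values equal Re(a1*y + a2), independent of a2."""
        t = np.linspace(0, 9, 300)
        for a1, a2 in [(1.0, 0.0), (2.0, -0.7)]:
            omega = 1.2
            a3 = (omega**2 + a2**2) / a1
            p = RiccatiParams(a1, a2, a3, r=0.6, tau_r=0.2)
            y = riccati_solution(p, t)
            fld = morphology_field(np.array([omega]), t, 0.6, 0.2)
            assert np.allclose(fld.values[0], (a1 * y + a2).real, atol=1e-10)

    def test_invalid_modulus_rejected(self):
        with pytest.raises(ValueError):
            morphology_field(np.array([1.0]), np.array([0.0]), r=1.0)


class TestHarmonicMap:
    def test_phi_zero_is_constant_minus_i(self):
        h = harmonic_map_h(HarmonicMapParams(0.0), np.linspace(-5, 5, 21))
        assert np.allclose(h, -1j, atol=1e-14)

    def test_exponent_collapse_at_phase_origin(self):
        h = harmonic_map_h(HarmonicMapParams(0.5, tau_m=0.0, omega=1.0), 0.0)
        assert complex(h) == pytest.approx(-1j * np.exp(-1.0), abs=1e-14)

    def test_known_quarter_phase_value(self):
        # 2*Omega*(t - tau_m) = pi/2
        h = harmonic_map_h(HarmonicMapParams(0.5, omega=1.0), np.pi / 4)
        assert complex(h) == pytest.approx(0.7615941559557649 - 0.6480542736638855j, abs=1e-12)

    @given(
        phi=st.floats(0.0, 1.5),
        theta=st.floats(-10.0, 10.0),
    )
    @settings(deadline=None, max_examples=60)
    def test_matches_trig_bracket_under_r_tanh_phi(self, phi, theta):
        """h equals the trigonometric bracket with r = tanh(Phi), Im flipped."""
        omega = 1.0
        t = theta / (2 * omega)
        h = complex(harmonic_map_h(HarmonicMapParams(phi, omega=omega), t))
        r = np.tanh(phi)
        denom = 1 + r**2 + 2 * r * np.cos(theta)
        bracket = (2 * r * np.sin(theta) + 1j * (1 - r**2)) / denom
        assert h.real == pytest.approx(bracket.real, abs=1e-12)
        assert h.imag == pytest.approx(-bracket.imag, abs=1e-12)

    def test_bounded_no_poles(self):
        """|h| stays within [(1-r)/(1+r), (1+r)/(1-r)] with r = tanh(Phi)."""
        t = np.linspace(-20, 20, 5001)
        r = np.tanh(2.5)
        h = harmonic_map_h(HarmonicMapParams(2.5, omega=3.0), t)
        assert np.all(np.isfinite(h))
        assert np.all(np.abs(h) <= (1 + r) / (1 - r) + 1e-9)
        assert np.all(np.abs(h) >= (1 - r) / (1 + r) - 1e-9)


class TestRegimeClassification:
    @pytest.mark.parametrize("r", [0.1, 0.5, 0.9])
    def test_slow_series_is_double_period(self, r):
        series, dt = canonical_trace(1.0, r)
        assert classify_regime(series, dt) is Regime.DOUBLE_PERIOD

    @pytest.mark.parametrize("r", [0.1, 0.5, 0.9])
    def test_fast_series_is_intermittency(self, r):
        series, dt = canonical_trace(10.0, r)
        assert classify_regime(series, dt) is Regime.INTERMITTENCY

    def test_zero_series_is_degenerate(self):
        series, dt = canonical_trace(1.0, 0.0)
        assert classify_regime(series, dt) is Regime.DEGENERATE

    def test_constant_series_is_degenerate(self):
        assert classify_regime(np.ones(1000), 0.01) is Regime.DEGENERATE

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            classify_regime(np.sin(np.linspace(0, 10, 100)), 0.1)

    def test_features_report_burst_timing(self):
        series, dt = canonical_trace(1.0, 0.5)
        f = regime_features(series, dt)
        # two bursts per period pi/Omega -> rate ~ 2/pi at Omega = 1
        assert f.burst_rate == pytest.approx(2 / np.pi, rel=0.1)
        assert f.gap_cluster_ratio > 1.05
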