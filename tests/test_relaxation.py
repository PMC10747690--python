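"""Spectral density, dipolar constant, relaxation rates and reports.

The spectral density is cross-checked against numerical cosine
transformation of the correlation function, and the dipolar constant
against step-by-step arithmetic with explicit CODATA constants.
"""

import numpy as np
import pytest
from scipy.integrate import quad

from spinrelax.correlation import ModelFreeParameters, evaluate_model_c
from spinrelax.relaxation import (
    RATIO_BOUNDS,
    PhysicalSettings,
    RelaxationResult,
    build_report,
    dipolar_constant,
    larmor_frequency,
    relaxation_rates,
    spectral_density,
)

PARAMS = ModelFreeParameters(tau_c=2000.0, tau_e=50.0, S2=0.8)


def random_params(rng):
    return ModelFreeParameters(
        tau_c=10 ** rng.uniform(1, 5),
        tau_e=10 ** rng.uniform(0, 4),
        S2=rng.uniform(0.0, 1.0),
    )


class TestLarmorFrequency:
    def test_zero_field(self):
        for conv in ("angular", "cyclic"):
            s = PhysicalSettings(b0_tesla=0.0, frequency_convention=conv)
            assert larmor_frequency(s) == 0.0

    def test_cyclic_product(self):
        s = PhysicalSettings(frequency_convention="cyclic")
        assert larmor_frequency(s) == pytest.approx(6.387e7, rel=1e-3)

    def test_angular_default(self):
        s = PhysicalSettings()
        assert larmor_frequency(s) == pytest.approx(
            2.0 * np.pi * 6.387e7, rel=1e-3
        )
        assert larmor_frequency(s) == pytest.approx(4.0130e8, rel=1e-3)


class TestSpectralDensity:
    def test_rigid_zero_frequency(self):
        p = ModelFreeParameters(tau_c=1000.0, tau_e=50.0, S2=1.0)
        assert spectral_density(p, 0.0) == pytest.approx(4.0e-10, rel=1e-12)

    def test_closed_form_with_internal_motion(self):
        # J(0) = (2/5)(S2 tau_c + (1-S2) tau) with tau = 48.78 ps
        val = spectral_density(PARAMS, 0.0)
        expected = 0.4 * (0.8 * 2e-9 + 0.2 * PARAMS.tau * 1e-12)
        assert val == pytest.approx(expected, rel=1e-12)
        assert val == pytest.approx(6.439e-10, rel=1e-3)

    @pytest.mark.parametrize("omega_factor", [0.0, 1.0, 2.0])
    def test_matches_numerical_cosine_transform(self, omega_factor):
        # J(w) = 2 * integral_0^inf C(t) cos(w t) dt, C in SI seconds
        omega = omega_factor * larmor_frequency(PhysicalSettings())

        # integrate in ps so the integrand is O(100) and quad's
        # tolerances are meaningful; convert the result to seconds
        def c_of_t_ps(t_ps):
            return evaluate_model_c(PARAMS, t_ps)

        omega_ps = omega * 1e-12  # rad/ps
        tail = 60.0 * PARAMS.tau_c
        kwargs = dict(limit=800, epsabs=1e-10, epsrel=1e-10)
        if omega_ps == 0.0:
            integral, _ = quad(c_of_t_ps, 0.0, tail, **kwargs)
        else:
            integral, _ = quad(
                c_of_t_ps, 0.0, tail, weight="cos", wvar=omega_ps, **kwargs
            )
        assert spectral_density(PARAMS, omega) == pytest.approx(
            2.0 * integral * 1e-12, rel=1e-6
        )

    def test_non_negative_and_non_increasing(self, rng):
        omegas = np.linspace(0.0, 5e9, 200)
        for _ in range(20):
            p = random_params(rng)
            j = spectral_density(p, omegas)
            assert np.all(j >= 0.0)
            assert np.all(np.diff(j) <= 1e-30)

    def test_negative_omega_rejected(self):
        with pytest.raises(ValueError, match="omega"):
            spectral_density(PARAMS, -1.0)


class TestDipolarConstant:
    def test_inverse_sixth_power_scaling(self):
        k1 = dipolar_constant(3.19).K
        k2 = dipolar_constant(6.38).K
        assert k2 / k1 == pytest.approx(1.0 / 64.0, rel=1e-12)

    def test_gamma_fourth_scaling(self):
        base = PhysicalSettings()
        double = PhysicalSettings(gamma_mhz_per_tesla=2 * 42.58)
        ratio = dipolar_constant(3.19, double).K / dipolar_constant(3.19, base).K
        assert ratio == pytest.approx(16.0, rel=1e-12)

    def test_constant_arithmetic_oracle(self):
        # independent step-by-step evaluation with explicit CODATA values
        mu0 = 1.25663706212e-6  # N A^-2
        hbar = 1.054571817e-34  # J s
        gamma = 2.0 * np.pi * 42.58e6  # rad/s/T
        spin = 0.5
        phi_m = 3.19e-10
        expected = (
            (mu0 / (4.0 * np.pi)) ** 2
            * 1.5
            * hbar**2
            * gamma**4
            * spin * (spin + 1.0)
            / phi_m**6
        )
        assert dipolar_constant(3.19).K == pytest.approx(expected, rel=1e-6)

    def test_planck_mode_h(self):
        import scipy.constants as const

        k_hbar = dipolar_constant(3.19).K
        k_h = dipolar_constant(3.19, PhysicalSettings(planck_mode="h")).K
        assert k_h / k_hbar == pytest.approx(
            (2.0 * np.pi) ** 2, rel=1e-9
        )
        assert const.h / const.hbar == pytest.approx(2 * np.pi)

    def test_heteronuclear_partner_gamma(self):
        # gamma^2 gamma_partner^2 replaces gamma^4
        s = PhysicalSettings(gamma_partner_mhz_per_tesla=42.58 / 2)
        assert dipolar_constant(3.19, s).K / dipolar_constant(
            3.19
        ).K == pytest.approx(0.25, rel=1e-12)

    def test_non_positive_phi_rejected(self):
        with pytest.raises(ValueError, match="phi"):
            dipolar_constant(0.0)


class TestRelaxationRates:
    def test_extreme_narrowing_ratios(self):
        # w0 tau -> 0 makes J equal at 0, w0, 2w0
        p = ModelFreeParameters(tau_c=1e-3, tau_e=1e-3, S2=0.8)
        K = dipolar_constant(3.19)
        r_printed = relaxation_rates(p, K, equation_set="as_printed")
        assert r_printed.ratio == pytest.approx(2.0 / 15.0, rel=1e-6)
        r_std = relaxation_rates(p, K, equation_set="standard_like_spin")
        assert r_std.ratio == pytest.approx(1.0, rel=1e-6)

    def test_hand_substitution_oracle(self):
        # independent end-to-end substitution for a rigid rotor
        p = ModelFreeParameters(tau_c=1000.0, tau_e=50.0, S2=1.0)
        settings = PhysicalSettings()
        K = dipolar_constant(3.19, settings)
        res = relaxation_rates(p, K, settings, "as_printed")

        w0 = 2.0 * np.pi * 42.58e6 * 1.5
        tau_c = 1e-9

        def j(w):
            return 0.4 * tau_c / (1.0 + (tau_c * w) ** 2)

        r1 = K.K * (j(w0) + j(2 * w0))
        r2 = K.K * (4 * j(0.0) + 10 * j(w0) + j(2 * w0))
        assert res.R1 == pytest.approx(r1, rel=1e-9)
        assert res.R2 == pytest.approx(r2, rel=1e-9)

    def test_reciprocal_identity(self, rng):
        K = dipolar_constant(3.5)
        for eq in ("as_printed", "standard_like_spin"):
            res = relaxation_rates(random_params(rng), K, equation_set=eq)
            assert res.T1 * res.R1 == pytest.approx(1.0, abs=1e-12)
            assert res.T2 * res.R2 == pytest.approx(1.0, abs=1e-12)

    def test_ratio_bounds_on_random_parameters(self, rng):
        # as_printed can never exceed 2/15; the conventional like-spin
        # set never exceeds 1 and keeps R2 >= R1
        K = dipolar_constant(3.19)
        for _ in range(200):
            p = random_params(rng)
            rp = relaxation_rates(p, K, equation_set="as_printed")
            assert rp.ratio <= RATIO_BOUNDS["as_printed"] + 1e-12
            rs = relaxation_rates(p, K, equation_set="standard_like_spin")
            assert rs.ratio <= RATIO_BOUNDS["standard_like_spin"] + 1e-12
            assert rs.R2 >= rs.R1 - 1e-15

    def test_standard_ratio_approaches_one_for_fast_motion(self):
        K = dipolar_constant(3.19)
        ratios = [
            relaxation_rates(
                ModelFreeParameters(tau_c=tc, tau_e=tc, S2=0.9),
                K,
                equation_set="standard_like_spin",
            ).ratio
            for tc in np.logspace(4, -1, 8)
        ]
        assert ratios == sorted(ratios)  # monotone toward the limit
        assert ratios[-1] == pytest.approx(1.0, abs=1e-4)

    def test_k_and_j_units_compose_to_rate(self):
        # scaling check: K ~ s^-2 and J ~ s combine to R ~ s^-1; halving
        # all times at zero field halves the rates
        K = dipolar_constant(3.19)
        p1 = ModelFreeParameters(tau_c=1000.0, tau_e=100.0, S2=0.7)
        p2 = ModelFreeParameters(tau_c=500.0, tau_e=50.0, S2=0.7)
        s0 = PhysicalSettings(b0_tesla=0.0)
        r1 = relaxation_rates(p1, K, s0)
        r2 = relaxation_rates(p2, K, s0)
        assert r2.R1 == pytest.approx(r1.R1 / 2.0, rel=1e-12)
        assert r2.R2 == pytest.approx(r1.R2 / 2.0, rel=1e-12)

    def test_unknown_equation_set_rejected(self):
        with pytest.raises(ValueError, match="equation_set"):
            relaxation_rates(PARAMS, dipolar_constant(3.19), equation_set="x")


class TestReport:
    def test_reciprocal_column_formatting(self):
        res = RelaxationResult.from_times(0.084, 0.056)
        df = build_report([("VC1 + WAT", res, 3.19)])
        assert df.loc[0, "R1_per_s"] == pytest.approx(11.905)
        assert df.loc[0, "R2_per_s"] == pytest.approx(17.857)

    def test_ratio_column(self):
        res = RelaxationResult.from_rates(11.905, 17.921)
        df = build_report([("VC1 + WAT", res, 3.19)])
        assert df.loc[0, "R1_over_R2"] == pytest.approx(0.664)

    def test_equal_rates_unit_ratio(self):
        res = RelaxationResult.from_rates(5.0, 5.0)
        df = build_report([("x", res, 3.5)])
        assert df.loc[0, "R1_over_R2"] == pytest.approx(1.000)

    def test_duplicate_labels_rejected(self):
        res = RelaxationResult.from_rates(5.0, 7.0)
        with pytest.raises(ValueError, match="duplicate"):
            build_report([("a", res, 3.2), ("a", res, 3.3)])

    def test_empty_report_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            build_report([])
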