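"""Single-level transport models: oracles, symmetries, limits."""

import math

import numpy as np
import pytest
from scipy.special import expit

from hemesam.constants import CONSTANTS
from hemesam.transport import (TransportParams, fermi_occupancy,
                               hopping_current, iv_curve, marcus_rate,
                               tunneling_current)


def dense_marcus_oracle(params, V, side):
    """Independent dense-grid trapezoid evaluation in raw energy space."""
    kT = CONSTANTS.k_B * params.temperature
    lam = params.lambda_reorg
    mu_l, mu_r = params.chemical_potentials(V)
    contact, direction = side.split("_")
    gamma = params.gamma_l if contact == "left" else params.gamma_r
    mu = float(mu_l if contact == "left" else mu_r)
    center = params.level_offset + (lam if direction == "in" else -lam)
    width = math.sqrt(4.0 * lam * kT)
    E = np.linspace(center - 12 * width, center + 12 * width, 400_001)
    kern = np.exp(-((E - center) ** 2) / (4 * lam * kT))
    occ = expit(-(E - mu) / kT) if direction == "in" else expit((E - mu) / kT)
    integral = np.trapezoid(kern * occ, E)
    return gamma / CONSTANTS.hbar * integral / math.sqrt(4 * math.pi * lam * kT)


class TestFermiOccupancy:
    def test_symmetry_point(self):
        assert fermi_occupancy(0.3, 0.3, 77.0) == 0.5

    def test_deep_tail_underflows_cleanly(self):
        val = fermi_occupancy(1.0, 0.0, 298.0)
        assert 0.0 <= val < 1e-16

    def test_matches_direct_evaluation(self):
        kT = CONSTANTS.k_B * 298.0
        direct = 1.0 / (1.0 + math.exp(-0.1 / kT))
        assert fermi_occupancy(-0.1, 0.0, 298.0) == pytest.approx(
            direct, rel=1e-12)

    def test_rejects_nonpositive_temperature(self):
        with pytest.raises(ValueError):
            fermi_occupancy(0.0, 0.0, 0.0)


class TestMarcusRate:
    def test_zero_coupling_gives_zero_rate(self):
        p = TransportParams("hopping", 0.5, 0.0, 0.01, lambda_reorg=0.5)
        assert marcus_rate(p, 0.5, "left_in") == 0.0

    def test_rate_positive_and_finite(self, rng):
        for _ in range(5):
            p = TransportParams(
                "hopping", rng.uniform(-0.5, 0.8), rng.uniform(1e-4, 0.05),
                rng.uniform(1e-4, 0.05), lambda_reorg=rng.uniform(0.1, 1.5))
            for side in ("left_in", "left_out", "right_in", "right_out"):
                r = marcus_rate(p, rng.uniform(-1, 1), side)
                assert np.isfinite(r) and r >= 0

    def test_matches_dense_grid_oracle(self):
        p = TransportParams("hopping", 0.5, 0.01, 0.01, lambda_reorg=0.5)
        got = marcus_rate(p, 0.5, "left_in")
        want = dense_marcus_oracle(p, 0.5, "left_in")
        assert got == pytest.approx(want, rel=1e-6)

    def test_oracle_agreement_random_draws(self, rng):
        """Adaptive quadrature vs independent dense trapezoid, both
        directions, random parameter draws."""
        for _ in range(20):
            p = TransportParams(
                "hopping", rng.uniform(-0.3, 0.7),
                10 ** rng.uniform(-3.5, -1.5), 10 ** rng.uniform(-3.5, -1.5),
                lambda_reorg=rng.uniform(0.15, 1.2),
                eta=rng.uniform(0.3, 0.7))
            V = rng.uniform(-1, 1)
            side = rng.choice(["left_in", "right_out", "left_out", "right_in"])
            got = marcus_rate(p, V, str(side))
            want = dense_marcus_oracle(p, V, str(side))
            assert got == pytest.approx(want, rel=1e-6)

    def test_grid_path_matches_adaptive(self, hop_params):
        for V in (-0.8, -0.2, 0.3, 1.0):
            a = marcus_rate(hop_params, V, "left_in")
            g = marcus_rate(hop_params, V, "left_in", method="grid")
            assert g == pytest.approx(a, rel=1e-8)

    def test_detailed_balance(self, hop_params):
        """in/out rate ratio at one electrode follows the Boltzmann
        factor of the level offset relative to that electrode."""
        kT = CONSTANTS.k_B * hop_params.temperature
        V = 0.4
        mu_l, _ = hop_params.chemical_potentials(V)
        rin = marcus_rate(hop_params, V, "left_in")
        rout = marcus_rate(hop_params, V, "left_out")
        expected = math.exp(-(hop_params.level_offset - float(mu_l)) / kT)
        assert rin / rout == pytest.approx(expected, rel=1e-6)


def master_equation_oracle(li, lo, ri, ro):
    """Symbolically solved steady state of the one-level master equation
    (sympy), independent of the implementation's algebra."""
    import sympy as sp

    P = sp.symbols("P")
    sol = sp.solve(sp.Eq((li + ri) * (1 - P), (lo + ro) * P), P)[0]
    return float(CONSTANTS.q * (ro * sol - ri * (1 - sol)))


class TestHoppingCurrent:
    def test_zero_bias_zero_current(self, hop_params):
        assert hopping_current(hop_params, 0.0) == pytest.approx(0.0, abs=1e-30)

    def test_antisymmetry_symmetric_junction(self, hop_params):
        V = np.linspace(0.1, 1.0, 7)
        Ip = hopping_current(hop_params, V, method="grid")
        Im = hopping_current(hop_params, -V, method="grid")
        assert np.allclose(Im, -Ip, rtol=1e-10)

    def test_matches_symbolic_master_equation(self, hop_params):
        V = 0.7
        rates = {s: marcus_rate(hop_params, V, s)
                 for s in ("left_in", "left_out", "right_in", "right_out")}
        want = master_equation_oracle(rates["left_in"], rates["left_out"],
                                      rates["right_in"], rates["right_out"])
        assert hopping_current(hop_params, V) == pytest.approx(want, rel=1e-10)

    def test_large_bias_reduces_to_series_form(self):
        """When backward rates vanish the current is the two-rate series
        combination q*R_in_l*R_out_r/(R_in_l+R_out_r)."""
        p = TransportParams("hopping", 0.1, 5e-3, 2e-3, lambda_reorg=0.3)
        V = 1.5
        li = marcus_rate(p, V, "left_in")
        ro = marcus_rate(p, V, "right_out")
        lo = marcus_rate(p, V, "left_out")
        ri = marcus_rate(p, V, "right_in")
        assert lo + ri < 1e-3 * (li + ro)  # regime check
        series = CONSTANTS.q * li * ro / (li + ro)
        assert hopping_current(p, V) == pytest.approx(series, rel=1e-2)

    def test_zero_coupling_zero_current(self):
        p = TransportParams("hopping", 0.3, 0.0, 5e-3, lambda_reorg=0.5)
        assert hopping_current(p, 0.8) == 0.0


class TestTunnelingCurrent:
    def test_zero_bias_zero_current(self, tun_params):
        for m in ("finite_T_integral", "zero_T_closed_form",
                  "finite_T_closed_form"):
            assert tunneling_current(tun_params, 0.0, method=m) == pytest.approx(
                0.0, abs=1e-25)

    def test_broken_series_path(self):
        p = TransportParams("tunneling", 0.8, 5e-3, 0.0)
        V = np.linspace(-1, 1, 11)
        assert np.all(tunneling_current(p, V) == 0.0)

    def test_finite_T_matches_closed_form_at_1K(self):
        p = TransportParams("tunneling", 0.8, 0.05, 0.05, temperature=1.0)
        V = np.linspace(-1, 1, 21)
        Ii = tunneling_current(p, V)
        Ic = tunneling_current(p, V, method="zero_T_closed_form")
        nz = np.abs(Ic) > 0
        assert np.max(np.abs(Ii[nz] - Ic[nz]) / np.abs(Ic[nz])) < 1e-5

    def test_digamma_form_matches_quadrature(self, tun_params):
        V = np.linspace(-1, 1, 11)
        Ii = tunneling_current(tun_params, V)
        Id = tunneling_current(tun_params, V, method="finite_T_closed_form")
        assert np.allclose(Ii, Id, rtol=1e-8, atol=1e-25)

    def test_zero_T_limit_error_decays_monotonically(self):
        errs = []
        for T in (300.0, 30.0, 3.0, 0.3):
            p = TransportParams("tunneling", 0.5, 0.02, 0.02, temperature=T)
            V = np.linspace(-1, 1, 21)
            Ii = tunneling_current(p, V, method="finite_T_closed_form")
            Ic = tunneling_current(p, V, method="zero_T_closed_form")
            errs.append(np.max(np.abs(Ii - Ic)))
        assert all(a > b for a, b in zip(errs, errs[1:]))

    def test_antisymmetry_symmetric_junction(self, tun_params):
        V = np.linspace(0.05, 1.0, 9)
        Ip = tunneling_current(tun_params, V, method="finite_T_closed_form")
        Im = tunneling_current(tun_params, -V, method="finite_T_closed_form")
        assert np.allclose(Im, -Ip, rtol=1e-12)


class TestIVCurve:
    def test_empty_voltages(self, tun_params):
        assert iv_curve(tun_params, [], 1e13).size == 0

    def test_single_voltage_consistency(self, tun_params):
        J = iv_curve(tun_params, [0.5], 1e13, fast=False)
        I = tunneling_current(tun_params, 0.5)
        assert J[0] == pytest.approx(I * 1e13, rel=1e-12)

    def test_density_scaling_is_linear(self, hop_params):
        V = np.linspace(-1, 1, 5)
        J1 = iv_curve(hop_params, V, 1e13)
        J2 = iv_curve(hop_params, V, 2e13)
        assert np.allclose(J2, 2 * J1, rtol=1e-12)

    def test_invalid_inputs(self, tun_params):
        with pytest.raises(ValueError):
            iv_curve(tun_params, [np.inf], 1e13)
        with pytest.raises(ValueError):
            iv_curve(tun_params, [0.1], 0.0)


class TestParamValidation:
    @pytest.mark.parametrize("kw", [
        dict(gamma_l=-1e-3), dict(eta=1.5), dict(temperature=-5.0),
    ])
    def test_invalid_params_rejected(self, kw):
        base = dict(mechanism="tunneling", level_offset=0.5,
                    gamma_l=1e-3, gamma_r=1e-3)
        base.update(kw)
        with pytest.raises(ValueError):
            TransportParams(**base)

    def test_hopping_requires_lambda(self):
        with pytest.raises(ValueError):
            TransportParams("hopping", 0.5, 1e-3, 1e-3)
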