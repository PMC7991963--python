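"""Zernike and LD/HD radial bases and the exact conversion between them.

The symbolic oracle (sympy) re-derives the high-degree modes by
Gram-Schmidt and the conversion matrix by monomial collection,
independently of the numpy implementation.
"""

import math

import numpy as np
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from cornealwave import (
    LDHDVector,
    OpticalZone,
    ZERNIKE_ORDERS,
    ZernikeVector,
    build_hd_modes,
    ldhd_mode,
    ldhd_to_zernike,
    ldhd_to_zernike_matrix,
    zernike_mode,
    zernike_to_ldhd,
    zernike_to_ldhd_matrix,
)

coeff = st.floats(-5.0, 5.0)


def _sympy_hd_modes():
    """Independent Gram-Schmidt on (rho^4, rho^6) under 2*int f g rho drho."""
    rho = sympy.Symbol("rho", positive=True)

    def inner(f, g):
        return sympy.integrate(2 * f * g * rho, (rho, 0, 1))

    v4 = rho**4
    g4 = v4 / sympy.sqrt(inner(v4, v4))
    v6 = rho**6 - inner(rho**6, g4) * g4
    g6 = v6 / sympy.sqrt(inner(v6, v6))
    return sympy.expand(g4), sympy.expand(g6), rho


class TestZernikeModes:
    def test_primary_sa_edge_value(self):
        # Z4(1) = sqrt(5) * (6 - 6 + 1)
        assert zernike_mode(4)(1.0) == pytest.approx(math.sqrt(5), abs=1e-12)

    def test_defocus_root(self):
        assert zernike_mode(2)(1 / math.sqrt(2)) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("order", ZERNIKE_ORDERS)
    def test_unit_rms_against_quadrature_oracle(self, order):
        mode = zernike_mode(order)
        ms, _ = quad(lambda r: 2 * mode(r) ** 2 * r, 0, 1)
        assert ms == pytest.approx(1.0, abs=1e-10)

    def test_unsupported_order_rejected(self):
        with pytest.raises(ValueError):
            zernike_mode(3)

    def test_gram_matrix_is_identity(self):
        modes = [zernike_mode(n) for n in ZERNIKE_ORDERS]
        gram = np.array([[a.inner(b) for b in modes] for a in modes])
        assert np.max(np.abs(gram - np.eye(4))) < 1e-10


class TestHDModes:
    def test_forms_match_symbolic_gram_schmidt(self):
        g4_sym, g6_sym, rho = _sympy_hd_modes()
        g4, g6 = build_hd_modes()
        for power, coef_num in zip((0, 2, 4, 6), g4.even_coeffs):
            assert coef_num == pytest.approx(float(g4_sym.coeff(rho, power)), abs=1e-12)
        for power, coef_num in zip((0, 2, 4, 6), g6.even_coeffs):
            assert coef_num == pytest.approx(float(g6_sym.coeff(rho, power)), abs=1e-12)
        # closed forms: G4 = sqrt(5) rho^4, G6 = sqrt(7)(6 rho^6 - 5 rho^4)
        assert g4(1.0) == pytest.approx(math.sqrt(5), abs=1e-12)
        assert g6.even_coeffs[3] == pytest.approx(6 * math.sqrt(7), abs=1e-12)

    def test_no_low_degree_monomials(self):
        for order in (4, 6):
            c = ldhd_mode(order).even_coeffs
            assert c[0] == 0.0 and c[1] == 0.0  # exactly no constant / rho^2 term

    def test_hd_gram_matrix_is_identity(self):
        g4, g6 = build_hd_modes()
        gram = np.array([[a.inner(b) for b in (g4, g6)] for a in (g4, g6)])
        assert np.max(np.abs(gram - np.eye(2))) < 1e-10

    def test_ld_modes_reuse_zernike_forms(self):
        assert ldhd_mode(0).even_coeffs == zernike_mode(0).even_coeffs
        assert ldhd_mode(2).even_coeffs == zernike_mode(2).even_coeffs


class TestConversion:
    def test_matrix_matches_symbolic_derivation(self):
        """Monomial collection in exact arithmetic reproduces the matrix."""
        rho = sympy.Symbol("rho", positive=True)
        z = [
            sympy.Integer(1),
            sympy.sqrt(3) * (2 * rho**2 - 1),
            sympy.sqrt(5) * (6 * rho**4 - 6 * rho**2 + 1),
            sympy.sqrt(7) * (20 * rho**6 - 30 * rho**4 + 12 * rho**2 - 1),
        ]
        g4_sym, g6_sym, _ = _sympy_hd_modes()
        g = [z[0], z[1], g4_sym, g6_sym]
        c_sym = sympy.symbols("c0 c2 c4 c6")
        wave = sympy.expand(sum(ci * zi for ci, zi in zip(c_sym, z)))
        g_sym = sympy.symbols("g0 g2 g4 g6")
        ansatz = sympy.expand(sum(gi * mi for gi, mi in zip(g_sym, g)))
        sol = sympy.solve(
            [sympy.Eq((wave - ansatz).coeff(rho, p), 0) for p in (0, 2, 4, 6)],
            g_sym,
        )
        M = zernike_to_ldhd_matrix()
        for i, gi in enumerate(g_sym):
            for j, cj in enumerate(c_sym):
                assert M[i, j] == pytest.approx(
                    float(sol[gi].coeff(cj)), abs=1e-12
                ), f"entry ({gi}, {cj})"

    def test_pure_defocus_passes_through(self, zone6):
        g = zernike_to_ldhd(ZernikeVector(0, 1, 0, 0, zone6))
        assert g.g2 == pytest.approx(1.0, abs=1e-12)
        assert g.g4 == pytest.approx(0.0, abs=1e-12)
        assert g.g6 == pytest.approx(0.0, abs=1e-12)

    def test_sa_to_defocus_coupling_factor(self, zone6):
        # c4 = -0.4 alone shifts g2 - c2 by -sqrt(15)*c4 = +1.5492
        g = zernike_to_ldhd(ZernikeVector(0, 0, -0.4, 0, zone6))
        assert g.g2 - 0.0 == pytest.approx(math.sqrt(15) * 0.4, abs=1e-10)
        assert g.g2 == pytest.approx(1.5492, abs=5e-5)

    def test_sixth_order_scaling(self, zone6):
        g = zernike_to_ldhd(ZernikeVector(0, 0, 0, 0.3, zone6))
        assert g.g6 == pytest.approx(1.0, abs=1e-12)  # (10/3) * 0.3

    def test_exact_ratios(self, zone6):
        c = ZernikeVector(0.0, 0.7, -0.3, 0.0, zone6)  # c6 = 0
        g = zernike_to_ldhd(c)
        assert (c.c2 - g.g2) / c.c4 == pytest.approx(math.sqrt(15), abs=1e-12)
        assert g.g4 / c.c4 == pytest.approx(6.0, abs=1e-12)

    @given(c0=coeff, c2=coeff, c4=coeff, c6=coeff)
    @settings(max_examples=100, derandomize=True)
    def test_round_trip_is_identity(self, c0, c2, c4, c6):
        zone = OpticalZone(6.0)
        c = ZernikeVector(c0, c2, c4, c6, zone)
        back = ldhd_to_zernike(zernike_to_ldhd(c))
        assert np.max(np.abs(back.as_array() - c.as_array())) < 1e-12

    def test_inverse_matrices_consistent(self):
        prod = ldhd_to_zernike_matrix() @ zernike_to_ldhd_matrix()
        assert np.max(np.abs(prod - np.eye(4))) < 1e-12

    def test_zero_vector_maps_to_zero(self, zone6):
        g = zernike_to_ldhd(ZernikeVector(0, 0, 0, 0, zone6))
        assert np.all(g.as_array() == 0.0)

    def test_hd_block_inversion_recovers_c4(self, zone6):
        # invert the 2x2 HD block: given g4 including a c6 coupling term
        c6 = 0.12
        g4 = 6 * (-0.4) - (40.0 / 3.0) * math.sqrt(7.0 / 5.0) * c6
        g6 = (10.0 / 3.0) * c6
        c = ldhd_to_zernike(LDHDVector(0.0, 0.0, g4, g6, zone6))
        assert c.c4 == pytest.approx(-0.4, abs=1e-12)
        assert c.c6 == pytest.approx(c6, abs=1e-12)

    @given(c0=coeff, c2=coeff, c4=coeff, c6=coeff)
    @settings(max_examples=100, derandomize=True)
    def test_pointwise_reconstruction_equality(self, c0, c2, c4, c6):
        """Both expansions describe the same polynomial on the disc."""
        zone = OpticalZone(6.0)
        c = ZernikeVector(c0, c2, c4, c6, zone)
        g = zernike_to_ldhd(c)
        rho = np.linspace(0.0, 1.0, 200)
        assert np.max(np.abs(c.evaluate(rho) - g.evaluate(rho))) < 1e-10

    def test_paraxial_matching_of_pure_quadratic(self, zone6):
        """Fitting W = a*rho^2 yields LD-only content with g2 = a/(2 sqrt(3))."""
        from cornealwave import project

        a = 2.5
        c = project(lambda r: a * (r / zone6.radius_mm) ** 2, zone6)
        g = zernike_to_ldhd(c)
        assert g.g4 == pytest.approx(0.0, abs=1e-10)
        assert g.g6 == pytest.approx(0.0, abs=1e-10)
        assert g.g2 == pytest.approx(a / (2 * math.sqrt(3)), abs=1e-10)
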