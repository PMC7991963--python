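"""Rotationally symmetric Zernike and low-degree/high-degree (LD/HD) bases.

Two orthonormal descriptions of a rotationally symmetric wavefront over the
unit disc are used, both restricted to even radial orders 0-6:

* the Zernike modes Z0, Z2 (defocus), Z4 (primary spherical aberration)
  and Z6 (secondary SA), unit-RMS under the disc inner product
  <f, g> = 2 * integral_0^1 f(rho) g(rho) rho drho;

* the LD/HD modes: the low-degree part reuses Z0 and Z2 (G0 = Z0,
  G2 = Z2), while the high-degree modes G4 and G6 are built by
  Gram-Schmidt orthonormalization of the pure monomials (rho^4, rho^6)
  and therefore contain no constant or quadratic term at all.

Because the HD modes are free of rho^2 content, the LD coefficient g2
carries the *entire* quadratic monomial of the wavefront (the paraxial
curvature of the fitted polynomial), whereas the Zernike c2 is polluted by
the -6rho^2 and +12rho^2 terms embedded in Z4 and Z6.  The exact linear
map between the two coefficient vectors is derived here at import time by
monomial bookkeeping (no hard-coded conversion floats):

    g6 = (10/3) c6
    g4 = 6 c4 - (40/3) sqrt(7/5) c6
    g2 = c2 - sqrt(15) c4 + 2 sqrt(21) c6
    g0 = c0 - 2 sqrt(5) c4 + 5 sqrt(7) c6

Coefficients are expressed in micrometers over a stated optical zone; they
are zone-specific and are never rescaled between zones here.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
import math

import numpy as np

from .geometry import OpticalZone

__all__ = [
    "RadialPolynomial",
    "ZERNIKE_ORDERS",
    "zernike_mode",
    "build_hd_modes",
    "ldhd_mode",
    "zernike_to_ldhd_matrix",
    "ldhd_to_zernike_matrix",
    "ZernikeVector",
    "LDHDVector",
    "zernike_to_ldhd",
    "ldhd_to_zernike",
]

#: Radial orders supported (rotationally symmetric, fit order 6).
ZERNIKE_ORDERS = (0, 2, 4, 6)


@dataclass(frozen=True)
class RadialPolynomial:
    """Even polynomial on the unit disc, coefficients of (1, rho^2, rho^4, rho^6)."""

    even_coeffs: tuple

    def __call__(self, rho):
        rho2 = np.asarray(rho, dtype=float) ** 2
        c = self.even_coeffs
        out = ((c[3] * rho2 + c[2]) * rho2 + c[1]) * rho2 + c[0]
        return out if np.ndim(out) else float(out)

    def inner(self, other: "RadialPolynomial") -> float:
        """Disc inner product <f, g> = 2 * int_0^1 f g rho drho (exact).

        For monomials, <rho^2i, rho^2j> = 1/(i + j + 1).
        """
        total = 0.0
        for i, a in enumerate(self.even_coeffs):
            for j, b in enumerate(other.even_coeffs):
                total += a * b / (i + j + 1)
        return total

    def rms(self) -> float:
        return math.sqrt(self.inner(self))


# Canonical radial Zernike polynomials R_n^0 (integer monomial tables) with
# the unit-RMS normalization sqrt(n+1).
_ZERNIKE_MONOMIALS = {
    0: (1,),
    2: (-1, 2),
    4: (1, -6, 6),
    6: (-1, 12, -30, 20),
}


def zernike_mode(order: int) -> RadialPolynomial:
    """Unit-RMS rotationally symmetric Zernike mode Z_n^0, n in {0, 2, 4, 6}."""
    if order not in _ZERNIKE_MONOMIALS:
        raise ValueError(f"unsupported radial order {order}; expected one of {ZERNIKE_ORDERS}")
    norm = math.sqrt(order + 1)
    coeffs = [0.0, 0.0, 0.0, 0.0]
    for k, c in enumerate(_ZERNIKE_MONOMIALS[order]):
        coeffs[k] = norm * c
    return RadialPolynomial(tuple(coeffs))


def _monomial_inner(i: int, j: int) -> Fraction:
    # <rho^2i, rho^2j> over the unit disc
    return Fraction(1, i + j + 1)


def build_hd_modes() -> tuple[RadialPolynomial, RadialPolynomial]:
    """High-degree modes (G4, G6) by Gram-Schmidt on (rho^4, rho^6).

    The orthonormalization is carried out in exact rational arithmetic
    under the disc inner product; only the final normalizations introduce
    square roots.  The result is G4 = sqrt(5) rho^4 and
    G6 = sqrt(7) (6 rho^6 - 5 rho^4); by construction neither contains a
    constant or rho^2 monomial.
    """
    # v4 = rho^4  -> exact coefficients over (1, rho^2, rho^4, rho^6)
    v4 = [Fraction(0), Fraction(0), Fraction(1), Fraction(0)]
    # v6 = rho^6 - proj_{v4}(rho^6)
    proj = _monomial_inner(3, 2) / _monomial_inner(2, 2)
    v6 = [Fraction(0), Fraction(0), -proj, Fraction(1)]

    def _normalize(v):
        norm2 = Fraction(0)
        for i, a in enumerate(v):
            for j, b in enumerate(v):
                norm2 += a * b * _monomial_inner(i, j)
        scale = 1.0 / math.sqrt(float(norm2))
        return RadialPolynomial(tuple(float(a) * scale for a in v))

    return _normalize(v4), _normalize(v6)


_HD_MODES = build_hd_modes()
_LDHD_MODES = {
    0: zernike_mode(0),  # G0 = Z0 (same analytic structure as the Zernike LD modes)
    2: zernike_mode(2),  # G2 = Z2
    4: _HD_MODES[0],
    6: _HD_MODES[1],
}


def ldhd_mode(order: int) -> RadialPolynomial:
    """LD/HD mode G_n^0: G0/G2 coincide with Z0/Z2; G4/G6 are the HD modes."""
    if order not in _LDHD_MODES:
        raise ValueError(f"unsupported radial order {order}; expected one of {ZERNIKE_ORDERS}")
    return _LDHD_MODES[order]


def _mode_matrix(modes) -> np.ndarray:
    # row k = monomial coefficients of mode k over (1, rho^2, rho^4, rho^6)
    return np.array([m.even_coeffs for m in modes], dtype=float)


_Z_MAT = _mode_matrix([zernike_mode(n) for n in ZERNIKE_ORDERS])
_G_MAT = _mode_matrix([ldhd_mode(n) for n in ZERNIKE_ORDERS])

# Equating monomial coefficients of sum(c_n Z_n) and sum(g_n G_n):
#   Z^T c = G^T g  =>  g = (G^T)^-1 Z^T c
_Z_TO_G = np.linalg.solve(_G_MAT.T, _Z_MAT.T)
_G_TO_Z = np.linalg.solve(_Z_MAT.T, _G_MAT.T)


def zernike_to_ldhd_matrix() -> np.ndarray:
    """4x4 matrix M with g = M @ (c0, c2, c4, c6), derived at import time."""
    return _Z_TO_G.copy()


def ldhd_to_zernike_matrix() -> np.ndarray:
    """Exact inverse map, c = M @ (g0, g2, g4, g6)."""
    return _G_TO_Z.copy()


@dataclass(frozen=True)
class ZernikeVector:
    """Zernike coefficients (um) of a rotationally symmetric map over a zone."""

    c0: float
    c2: float
    c4: float
    c6: float
    zone: OpticalZone

    def as_array(self) -> np.ndarray:
        return np.array([self.c0, self.c2, self.c4, self.c6], dtype=float)

    def evaluate(self, rho):
        """Reconstruct the map (um) at unit-disc radius rho."""
        return sum(
            c * zernike_mode(n)(rho)
            for c, n in zip(self.as_array(), ZERNIKE_ORDERS)
        )

    @classmethod
    def from_array(cls, arr, zone: OpticalZone) -> "ZernikeVector":
        c0, c2, c4, c6 = (float(x) for x in arr)
        return cls(c0, c2, c4, c6, zone)


@dataclass(frozen=True)
class LDHDVector:
    """LD/HD coefficients (um) over a zone; g4/g6 weight the HD modes."""

    g0: float
    g2: float
    g4: float
    g6: float
    zone: OpticalZone

    def as_array(self) -> np.ndarray:
        return np.array([self.g0, self.g2, self.g4, self.g6], dtype=float)

    def evaluate(self, rho):
        return sum(
            g * ldhd_mode(n)(rho)
            for g, n in zip(self.as_array(), ZERNIKE_ORDERS)
        )

    @classmethod
    def from_array(cls, arr, zone: OpticalZone) -> "LDHDVector":
        g0, g2, g4, g6 = (float(x) for x in arr)
        return cls(g0, g2, g4, g6, zone)


def zernike_to_ldhd(c: ZernikeVector) -> LDHDVector:
    """Convert a Zernike coefficient vector to the LD/HD basis (same zone)."""
    return LDHDVector.from_array(_Z_TO_G @ c.as_array(), c.zone)


def ldhd_to_zernike(g: LDHDVector) -> ZernikeVector:
    """Convert an LD/HD coefficient vector back to the Zernike basis."""
    return ZernikeVector.from_array(_G_TO_Z @ g.as_array(), g.zone)
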