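"""Scalar-product Zernike projection of rotationally symmetric maps.

A surface elevation (or wavefront) profile ``W(r)`` in micrometers over a
zone of diameter ``S`` is expanded on the rotationally symmetric Zernike
modes up to radial order 6 by orthogonal projection::

    c_n = <W, Z_n> = 2 * int_0^1 W(rho * S/2) Z_n(rho) rho drho

evaluated with a fixed-order Gauss-Legendre rule (64 nodes by default)
after substituting out the rho weight.  The rule is deterministic, so all
downstream coefficients are bit-stable, and it is exact to machine
precision for polynomial integrands far beyond degree 12.

For a conic surface the order-6 expansion is an approximation: the conic
has even-order content at all orders, and the part beyond rho^6 both
leaves a reconstruction residual and leaks into the fitted coefficients.
``reconstruction_residual_rms`` reports that residual rather than hiding
it.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .bases import ZERNIKE_ORDERS, ZernikeVector, zernike_mode
from .geometry import ConicSurface, OpticalZone

__all__ = [
    "DEFAULT_QUAD_ORDER",
    "project",
    "surface_elevation_um",
    "project_surface",
    "project_surface_pair",
    "reconstruction_residual_rms",
]

#: Gauss-Legendre node count for all scalar products.
DEFAULT_QUAD_ORDER = 64


@lru_cache(maxsize=8)
def _nodes(order: int):
    x, w = np.polynomial.legendre.leggauss(order)
    rho = 0.5 * (x + 1.0)
    weight = 0.5 * w
    return rho, weight


@lru_cache(maxsize=8)
def _mode_table(order: int):
    rho, weight = _nodes(order)
    # row n: 2 * w_i * rho_i * Z_n(rho_i), so c_n = table @ W(values)
    return np.array([2.0 * weight * rho * zernike_mode(n)(rho) for n in ZERNIKE_ORDERS])


def project(fn, zone: OpticalZone, quad_order: int = DEFAULT_QUAD_ORDER) -> ZernikeVector:
    """Project a radial map onto Z0, Z2, Z4, Z6 over the zone.

    Parameters
    ----------
    fn
        Callable mapping physical radius r (mm, vectorized) on [0, S/2] to
        elevation or phase in micrometers.
    zone
        Optical zone defining the unit-disc normalization radius S/2.
    quad_order
        Gauss-Legendre node count.
    """
    rho, _ = _nodes(quad_order)
    values = np.asarray(fn(rho * zone.radius_mm), dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("radial function returned non-finite values on the zone")
    coeffs = _mode_table(quad_order) @ values
    return ZernikeVector.from_array(coeffs, zone)


def surface_elevation_um(surface: ConicSurface):
    """Sagittal elevation of a conic as a radial map in micrometers."""
    return lambda r_mm: 1000.0 * surface.sagitta(r_mm)


def project_surface(
    surface: ConicSurface,
    zone: OpticalZone,
    quad_order: int = DEFAULT_QUAD_ORDER,
) -> ZernikeVector:
    """Zernike coefficients (um) of a conic surface's elevation over a zone."""
    surface.validate_zone(zone)  # fail at the zone edge, not mid-quadrature
    return project(surface_elevation_um(surface), zone, quad_order)


def project_surface_pair(
    pre: ConicSurface,
    post: ConicSurface,
    zone: OpticalZone,
    quad_order: int = DEFAULT_QUAD_ORDER,
) -> tuple[ZernikeVector, ZernikeVector]:
    """Project pre- and post-operative conics with one quadrature rule."""
    return (
        project_surface(pre, zone, quad_order),
        project_surface(post, zone, quad_order),
    )


def reconstruction_residual_rms(
    fn,
    coeffs: ZernikeVector,
    quad_order: int = 2 * DEFAULT_QUAD_ORDER,
) -> float:
    """RMS (um) of the part of ``fn`` not captured by the order-6 fit.

    Computed as sqrt(2 * int_0^1 (W - sum c_n Z_n)^2 rho drho); zero (to
    quadrature accuracy) iff ``fn`` is an even polynomial of degree <= 6.
    """
    rho, weight = _nodes(quad_order)
    values = np.asarray(fn(rho * coeffs.zone.radius_mm), dtype=float)
    resid = values - coeffs.evaluate(rho)
    return float(np.sqrt(np.sum(2.0 * weight * rho * resid**2)))
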