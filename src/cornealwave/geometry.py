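"""Conic-section corneal geometry.

The anterior corneal surface is modeled as a rotationally symmetric conic
section described by two parameters: the apical radius of curvature ``R``
(mm) and the asphericity ``Q`` (conic constant).  ``Q = 0`` is a sphere,
``Q < 0`` a prolate surface that flattens toward the periphery (``Q = -1``
is a paraboloid), ``Q > 0`` an oblate surface that steepens peripherally.

A refractive correction of ``D`` diopters at the corneal plane maps the
pre-operative apical radius to the post-operative one through the paraxial
thin-surface power formula for the air/stroma interface (refractive index
step 1.0 -> 1.376).  The ablation profile itself is the vertical gap
between the two conics over the optical zone, offset so that tissue removal
is nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConicDomainError",
    "ConicSurface",
    "OpticalZone",
    "RefractiveConstants",
    "AIR_TO_STROMA",
    "postop_radius",
    "AblationProfile",
]


class ConicDomainError(ValueError):
    """Raised when a conic surface is evaluated beyond its valid extent."""


@dataclass(frozen=True)
class OpticalZone:
    """Analysis/ablation zone of diameter ``S`` (mm).

    The zone defines the normalization radius ``S/2`` mapping physical
    radius ``r`` to the unit-disc coordinate ``rho = 2r/S``.
    """

    diameter_mm: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.diameter_mm) or self.diameter_mm <= 0:
            raise ValueError(f"zone diameter must be positive, got {self.diameter_mm}")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0


@dataclass(frozen=True)
class RefractiveConstants:
    """Refractive indices at the ablation interface.

    The wavefront change produced by reshaping the anterior cornea is the
    elevation change times ``delta_n = n_stroma - n_air`` (0.376 for the
    air-to-stroma step).
    """

    n_air: float = 1.0
    n_stroma: float = 1.376

    @property
    def delta_n(self) -> float:
        return self.n_stroma - self.n_air


#: Default air -> corneal stroma interface (n = 1.0 -> n' = 1.376).
AIR_TO_STROMA = RefractiveConstants()


@dataclass(frozen=True)
class ConicSurface:
    """Rotationally symmetric conic corneal profile.

    Parameters
    ----------
    apical_radius_mm
        Radius of curvature at the apex, mm (> 0).
    asphericity_q
        Conic constant Q (dimensionless).
    """

    apical_radius_mm: float
    asphericity_q: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.apical_radius_mm) or self.apical_radius_mm <= 0:
            raise ValueError(
                f"apical radius must be positive, got {self.apical_radius_mm}"
            )
        if not np.isfinite(self.asphericity_q):
            raise ValueError("asphericity must be finite")

    def sagitta(self, r_mm):
        """Axial elevation z(r) (mm), positive toward the retina.

        z(r) = r^2 / ( R * (1 + sqrt(1 - (1+Q) r^2 / R^2)) )

        This form is exact for every Q (for Q = -1 it reduces to the
        paraboloid r^2 / 2R) and is numerically stable at the apex.

        Raises
        ------
        ConicDomainError
            If ``1 - (1+Q) r^2/R^2 <= 0``, i.e. the requested radius lies
            beyond the extent where the conic is defined.
        """
        r = np.asarray(r_mm, dtype=float)
        if np.any(r < 0):
            raise ValueError("radial distance must be nonnegative")
        R = self.apical_radius_mm
        arg = 1.0 - (1.0 + self.asphericity_q) * (r / R) ** 2
        if np.any(arg <= 0.0):
            raise ConicDomainError(
                f"conic (R={R} mm, Q={self.asphericity_q}) undefined at "
                f"r={np.max(r):g} mm: zone exceeds the conic's valid extent"
            )
        out = r**2 / (R * (1.0 + np.sqrt(arg)))
        return out if out.ndim else float(out)

    def validate_zone(self, zone: OpticalZone) -> None:
        """Raise :class:`ConicDomainError` if the zone edge is outside the
        conic's valid domain."""
        self.sagitta(zone.radius_mm)


def postop_radius(
    r0_mm: float,
    d_diopters: float,
    constants: RefractiveConstants = AIR_TO_STROMA,
) -> float:
    """Post-operative apical radius from a paraxial defocus correction.

    The correction ``D`` (diopters, corneal plane) changes the paraxial
    surface power ``(n' - n)/R``::

        1/R1 = 1/R0 + D / (n' - n)        (radii in meters)

    so a hyperopic correction (D > 0) steepens the cornea (R1 < R0) and a
    myopic one (D < 0) flattens it.

    Raises
    ------
    ValueError
        If the correction would flatten the surface to nonpositive power.
    """
    # radii handled in mm: D/(n'-n) [1/m] == D/(1000*(n'-n)) [1/mm]
    curvature = 1.0 / r0_mm + d_diopters / (1000.0 * constants.delta_n)
    if curvature <= 0.0:
        raise ValueError(
            f"correction {d_diopters} D on R0={r0_mm} mm yields nonpositive "
            "paraxial power"
        )
    return 1.0 / curvature


@dataclass(frozen=True)
class AblationProfile:
    """Tissue-removal profile between two conic surfaces over a zone.

    The ablation thickness at radius ``r`` is the vertical gap between the
    post- and pre-operative conics plus the central depth offset ``t0``::

        t(r) = 1000 * (z_post(r) - z_pre(r)) + t0     [um]

    When ``central_depth_um`` is not supplied, ``t0`` is chosen so that the
    minimum thickness over the zone is exactly zero (no tissue addition).
    The profile is diagnostic only; coefficient computations depend on the
    surfaces alone.
    """

    pre: ConicSurface
    post: ConicSurface
    zone: OpticalZone
    central_depth_um: float = field(default=None)  # type: ignore[assignment]

    _GRID_POINTS = 2049

    def __post_init__(self) -> None:
        self.pre.validate_zone(self.zone)
        self.post.validate_zone(self.zone)
        if self.central_depth_um is None:
            r = np.linspace(0.0, self.zone.radius_mm, self._GRID_POINTS)
            gap = 1000.0 * (self.post.sagitta(r) - self.pre.sagitta(r))
            object.__setattr__(self, "central_depth_um", float(-np.min(gap)))
        elif self.central_depth_um < 0:
            raise ValueError("central ablation depth must be nonnegative")

    def thickness_um(self, r_mm):
        """Ablation depth t(r) in um for r within the zone."""
        r = np.asarray(r_mm, dtype=float)
        if np.any(r > self.zone.radius_mm * (1 + 1e-12)):
            raise ValueError("radius outside the optical zone")
        gap = 1000.0 * (self.post.sagitta(r) - self.pre.sagitta(r))
        out = gap + self.central_depth_um
        return out if np.ndim(out) else float(out)
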