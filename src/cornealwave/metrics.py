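"""Wavefront deltas and dioptric metrics.

Surface-coefficient changes become wavefront changes through the
refractive-index step at the ablation interface:

    dz_n = (c_n_post - c_n_pre) * (n' - n)          [um, (n'-n) = 0.376]

and the LD/HD delta follows by applying the (linear) basis conversion to
the Zernike delta.  The dioptric spherical equivalent of a defocus
coefficient c (um) over a zone of diameter S (mm) is

    SE = 4 sqrt(3) c / (S/2)^2                      [D]

with the positive sign meaning increased corneal power; the clinically
read refraction shift is its negative (a power increase makes the eye
more myopic, i.e. shifts the subjective refraction in the minus
direction).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

from .bases import LDHDVector, ZernikeVector, zernike_to_ldhd
from .geometry import AIR_TO_STROMA, OpticalZone, RefractiveConstants

__all__ = [
    "WavefrontDelta",
    "wavefront_delta",
    "spherical_equivalent",
    "refraction_shift",
]

_4SQRT3 = 4.0 * sqrt(3.0)


def spherical_equivalent(c2_um: float, zone: OpticalZone) -> float:
    """Dioptric spherical equivalent of a defocus coefficient.

    ``SE = 4 sqrt(3) c2 / (S/2)^2`` with c2 in um and S/2 in mm.  Positive
    SE corresponds to an increase of corneal power.
    """
    return _4SQRT3 * c2_um / zone.radius_mm**2


def refraction_shift(dse_diopters: float) -> float:
    """Subjective-refraction shift implied by a corneal power change.

    A power increase of +1 D makes the eye 1 D more myopic: the refraction
    moves by -1 D, hence the sign flip.
    """
    return -dse_diopters


@dataclass(frozen=True)
class WavefrontDelta:
    """Wavefront change in both bases, with dioptric summaries.

    ``dz`` and ``dg`` describe the same polynomial change (pointwise equal
    after basis expansion); ``dse_zernike``/``dse_ldhd`` are the spherical
    equivalents of the two defocus deltas.
    """

    dz: ZernikeVector
    dg: LDHDVector
    dse_zernike: float
    dse_ldhd: float

    @property
    def zone(self) -> OpticalZone:
        return self.dz.zone

    @property
    def shift_zernike(self) -> float:
        """Refraction shift read from the Zernike defocus delta (D)."""
        return refraction_shift(self.dse_zernike)

    @property
    def shift_ldhd(self) -> float:
        """Refraction shift read from the LD/HD defocus delta (D)."""
        return refraction_shift(self.dse_ldhd)


def wavefront_delta(
    pre_c: ZernikeVector,
    post_c: ZernikeVector,
    constants: RefractiveConstants = AIR_TO_STROMA,
) -> WavefrontDelta:
    """Wavefront change between two surface-coefficient vectors.

    Both vectors must be expressed over the same zone.  The LD/HD delta is
    obtained by converting the Zernike delta (equivalently: converting
    each vector and subtracting; the conversion is linear).
    """
    if pre_c.zone != post_c.zone:
        raise ValueError(
            f"zone mismatch: {pre_c.zone.diameter_mm} mm vs {post_c.zone.diameter_mm} mm"
        )
    zone = pre_c.zone
    dz = ZernikeVector.from_array(
        (post_c.as_array() - pre_c.as_array()) * constants.delta_n, zone
    )
    dg = zernike_to_ldhd(dz)
    return WavefrontDelta(
        dz=dz,
        dg=dg,
        dse_zernike=spherical_equivalent(dz.c2, zone),
        dse_ldhd=spherical_equivalent(dg.g2, zone),
    )
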