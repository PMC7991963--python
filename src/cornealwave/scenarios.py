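"""End-to-end ablation simulation scenarios.

Each scenario composes the same pipeline: the paraxial formula gives the
post-operative apical radius from the planned correction D, the target
asphericity Q1 comes from the plan (fixed, conventional Q1 = Q0, or solved
so that the fourth-order Zernike SA changes by a prescribed amount), both
conics are projected onto the order-6 Zernike basis over the optical zone,
and the coefficient difference times 0.376 gives the wavefront change in
both bases together with the spherical-equivalent summaries.

Four studies are provided:

* a spherical sweep (conventional profiles, Q0 = Q1 = 0) across planned
  corrections, showing the Zernike-defocus SE overshooting the plan;
* an optical-zone sweep at fixed correction, showing the LD/HD defocus SE
  staying at the plan while the Zernike one drifts with zone diameter;
* asphericity sweeps at zero paraxial correction (custom profiles that
  only change Q), showing the spurious Zernike defocus change;
* a presbyopia table: hyperopic corrections with Q1 solved so that the
  Zernike primary SA changes by a fixed negative amount.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .geometry import (
    AIR_TO_STROMA,
    ConicSurface,
    OpticalZone,
    RefractiveConstants,
    postop_radius,
)
from .metrics import WavefrontDelta, wavefront_delta
from .projection import DEFAULT_QUAD_ORDER, project_surface, project_surface_pair

__all__ = [
    "SolverError",
    "AblationPlan",
    "ScenarioResult",
    "solve_q1_for_target_dz4",
    "run_plan",
    "run_spherical_sweep",
    "run_zone_sweep",
    "run_asphericity_sweep",
    "presbyopia_table",
    "DEFAULT_D_GRID",
    "DEFAULT_S_GRID",
]

logger = logging.getLogger(__name__)

#: Planned-correction grid for the spherical sweep (D, 1-diopter steps).
DEFAULT_D_GRID = tuple(float(d) for d in range(-10, 7))
#: Optical-zone grid for the zone sweep (mm, 0.5 mm steps).
DEFAULT_S_GRID = tuple(np.arange(5.0, 8.01, 0.5))

_Q1_BRACKET = (-3.0, 1.0)


class SolverError(RuntimeError):
    """Raised when the asphericity solver cannot bracket a root."""


@dataclass(frozen=True)
class AblationPlan:
    """Planned correction: defocus D plus an asphericity target.

    Exactly one of ``target_q1`` (explicit post-operative asphericity) or
    ``target_dz4_um`` (solve Q1 so the fourth-order Zernike wavefront
    coefficient changes by this amount) may be set; with neither, the
    profile is conventional (Q1 = Q0).
    """

    preop: ConicSurface
    zone: OpticalZone
    d_correction: float = 0.0
    target_q1: float | None = None
    target_dz4_um: float | None = None

    def __post_init__(self) -> None:
        if self.target_q1 is not None and self.target_dz4_um is not None:
            raise ValueError("set at most one of target_q1 and target_dz4_um")


@dataclass(frozen=True)
class ScenarioResult:
    """One simulated correction: plan echo, post-op conic, wavefront delta."""

    plan: AblationPlan
    postop: ConicSurface
    delta: WavefrontDelta

    @property
    def d(self) -> float:
        return self.plan.d_correction

    @property
    def zone(self) -> OpticalZone:
        return self.plan.zone

    @property
    def r0(self) -> float:
        return self.plan.preop.apical_radius_mm

    @property
    def q0(self) -> float:
        return self.plan.preop.asphericity_q

    @property
    def r1(self) -> float:
        return self.postop.apical_radius_mm

    @property
    def q1(self) -> float:
        return self.postop.asphericity_q

    @property
    def dq(self) -> float:
        return self.q1 - self.q0


def solve_q1_for_target_dz4(
    preop: ConicSurface,
    d_correction: float,
    zone: OpticalZone,
    dz4_target_um: float,
    constants: RefractiveConstants = AIR_TO_STROMA,
    bracket: tuple[float, float] = _Q1_BRACKET,
    xtol: float = 1e-8,
    quad_order: int = DEFAULT_QUAD_ORDER,
) -> float:
    """Post-operative asphericity producing a prescribed Zernike SA change.

    Finds the root of ``f(Q1) = (n'-n) * (c4(R1, Q1) - c4(R0, Q0)) -
    dz4_target`` over the zone, where R1 follows from the paraxial
    correction.  ``f`` is monotone increasing in Q1 (a more oblate surface
    has more positive peripheral curvature, hence more positive SA), so a
    bracketing root-finder is reliable.

    Raises
    ------
    SolverError
        If ``f`` does not change sign over the bracket.
    """
    r1 = postop_radius(preop.apical_radius_mm, d_correction, constants)
    c4_pre = project_surface(preop, zone, quad_order).c4

    def f(q1: float) -> float:
        c4_post = project_surface(ConicSurface(r1, q1), zone, quad_order).c4
        return constants.delta_n * (c4_post - c4_pre) - dz4_target_um

    lo, hi = bracket
    f_lo, f_hi = f(lo), f(hi)
    if f_lo * f_hi > 0:
        raise SolverError(
            f"target dz4={dz4_target_um} um not bracketable for Q1 in "
            f"[{lo}, {hi}] (R0={preop.apical_radius_mm}, Q0={preop.asphericity_q}, "
            f"D={d_correction}, S={zone.diameter_mm}): f({lo})={f_lo:.4g}, "
            f"f({hi})={f_hi:.4g}"
        )
    q1, results = brentq(f, lo, hi, xtol=xtol, full_output=True)
    logger.debug(
        "Q1 solver: D=%+.2f target dz4=%.4f um -> Q1=%.6f in %d iterations",
        d_correction, dz4_target_um, q1, results.iterations,
    )
    return float(q1)


def run_plan(
    plan: AblationPlan,
    constants: RefractiveConstants = AIR_TO_STROMA,
    quad_order: int = DEFAULT_QUAD_ORDER,
) -> ScenarioResult:
    """Simulate one planned correction end to end."""
    r1 = postop_radius(plan.preop.apical_radius_mm, plan.d_correction, constants)
    if plan.target_dz4_um is not None:
        q1 = solve_q1_for_target_dz4(
            plan.preop, plan.d_correction, plan.zone, plan.target_dz4_um,
            constants, quad_order=quad_order,
        )
    elif plan.target_q1 is not None:
        q1 = plan.target_q1
    else:
        q1 = plan.preop.asphericity_q
    postop = ConicSurface(r1, q1)
    try:
        pre_c, post_c = project_surface_pair(plan.preop, postop, plan.zone, quad_order)
    except ValueError as exc:
        raise ValueError(
            f"plan failed (R0={plan.preop.apical_radius_mm}, "
            f"Q0={plan.preop.asphericity_q}, D={plan.d_correction}, "
            f"Q1={q1}, S={plan.zone.diameter_mm}): {exc}"
        ) from exc
    return ScenarioResult(plan=plan, postop=postop,
                          delta=wavefront_delta(pre_c, post_c, constants))


def run_spherical_sweep(
    r0_mm: float = 7.8,
    d_values=DEFAULT_D_GRID,
    zone: OpticalZone = OpticalZone(6.0),
    constants: RefractiveConstants = AIR_TO_STROMA,
) -> list[ScenarioResult]:
    """Conventional spherical profiles (Q0 = Q1 = 0) across corrections."""
    preop = ConicSurface(r0_mm, 0.0)
    return [
        run_plan(AblationPlan(preop, zone, d_correction=float(d), target_q1=0.0),
                 constants)
        for d in d_values
    ]


def run_zone_sweep(
    r0_mm: float = 7.8,
    d_correction: float = -6.0,
    s_values=DEFAULT_S_GRID,
    constants: RefractiveConstants = AIR_TO_STROMA,
) -> list[ScenarioResult]:
    """One spherical correction analyzed over a range of zone diameters."""
    preop = ConicSurface(r0_mm, 0.0)
    return [
        run_plan(
            AblationPlan(preop, OpticalZone(float(s)), d_correction=d_correction,
                         target_q1=0.0),
            constants,
        )
        for s in s_values
    ]


def run_asphericity_sweep(
    preop: ConicSurface,
    dq_values,
    zone: OpticalZone = OpticalZone(6.0),
    constants: RefractiveConstants = AIR_TO_STROMA,
) -> list[ScenarioResult]:
    """Custom aspheric profiles changing only Q (paraxial correction D = 0)."""
    return [
        run_plan(
            AblationPlan(preop, zone, d_correction=0.0,
                         target_q1=preop.asphericity_q + float(dq)),
            constants,
        )
        for dq in dq_values
    ]


def presbyopia_table(
    r0_mm: float = 7.8,
    q0: float = -0.2,
    zone: OpticalZone = OpticalZone(6.0),
    dz4_target_um: float = -0.40,
    d_values=(2.0, 4.0, 6.0),
    constants: RefractiveConstants = AIR_TO_STROMA,
) -> list[ScenarioResult]:
    """Presbyopic custom ablations: fixed negative SA target per correction.

    For each hyperopic correction D the post-operative asphericity is
    solved so the fourth-order Zernike wavefront coefficient changes by
    ``dz4_target_um`` (default -0.40 um), steepening the center while
    flattening the periphery (a varifocal, depth-of-focus-extending
    profile).
    """
    preop = ConicSurface(r0_mm, q0)
    return [
        run_plan(
            AblationPlan(preop, zone, d_correction=float(d),
                         target_dz4_um=dz4_target_um),
            constants,
        )
        for d in d_values
    ]
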