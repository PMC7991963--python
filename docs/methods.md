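# Methods

## Surface model

The anterior cornea is modeled as a rotationally symmetric conic with two
parameters: apical radius `R` (mm) and asphericity `Q`.  The sagitta is
evaluated in the rationalized form
`z(r) = r^2 / (R (1 + sqrt(1 - (1+Q) r^2/R^2)))`, which is exact for all
`Q` (it degenerates smoothly to the paraboloid `r^2/2R` at `Q = -1`) and
avoids cancellation near the apex.  Evaluation outside the conic's valid
extent (`(1+Q) r^2 >= R^2`) raises a domain error rather than returning a
complex or clipped value.  Real corneas have more degrees of freedom than
`(R, Q)`; the model deliberately ignores transition zones outside the
optical zone, ablation efficiency ("cosine effect"), and biomechanical or
epithelial remodeling, so its outputs are the *intended* optical change of
an idealized profile, not a prediction of healed topography.

## Paraxial correction

A planned defocus correction `D` (diopters at the corneal plane) changes
the paraxial power of the air/stroma interface, `(n'-1)/R` with
`n' = 1.376`:

    1/R1 = 1/R0 + D/(n' - 1)        (radii in meters)

Hyperopic corrections (`D > 0`) steepen the surface, myopic ones flatten
it.  The formula is an involution (undoing `D` restores `R0` to < 1e-9 mm)
and reproduces the planned power exactly by construction.  The
keratometric index 1.3375 is *not* used anywhere: the simulated quantity
is the optical-path change at the interface, for which only the true index
step 0.376 is meaningful.

## Projection and fit order

A surface elevation (mm, converted to µm at the projection boundary) over
a zone of diameter `S` is expanded on the rotationally symmetric Zernike
modes up to radial order 6 by scalar products under the disc inner product
`<f,g> = 2 * int_0^1 f g rho drho`.  The integrals use a fixed 64-node
Gauss–Legendre rule on `rho in [0,1]` after absorbing the `rho` weight —
deterministic, bit-stable, and exact to machine precision for polynomial
integrands of the degrees that occur here (doubling the node count moves
conic coefficients by < 1e-9 µm).  No least-squares fitting on sampled
grids is performed.

The order-6 expansion of a conic is an approximation: a conic has even
monomial content at every order, and the part beyond `rho^6` both leaves a
reconstruction residual (reported by `reconstruction_residual_rms`, about
0.02 µm RMS for typical corneas on 6 mm) and leaks slightly into every
fitted coefficient.  Two visible consequences, quantified below, are that
the "null" LD/HD defocus of zero-diopter aspheric profiles is null only to
about 0.01 µm, and that the higher-order coefficients grow slightly
faster than the leading `S^4`/`S^6` power laws across zone diameters.

## The LD/HD basis and the conversion

The low-degree modes reuse the Zernike forms (`G0 = Z0`,
`G2 = sqrt(3)(2 rho^2 - 1)`).  The high-degree modes are built by
Gram–Schmidt orthonormalization of the pure monomials `(rho^4, rho^6)`
under the disc inner product, carried out in exact rational arithmetic at
import time (square roots enter only in the final normalization):
`G4 = sqrt(5) rho^4`, `G6 = sqrt(7)(6 rho^6 - 5 rho^4)`.  By construction
they contain no constant or quadratic monomial, so all `rho^2` content of
a fitted wavefront lands in `g2` — the paraxial-curvature reading of the
fit.

The coefficient conversion is obtained by equating monomial coefficients
of the two expansions (a triangular 4×4 solve of the mode matrices, not
hard-coded floats).  In closed form:

    g6 = (10/3) c6
    g4 = 6 c4 - (40/3) sqrt(7/5) c6
    g2 = c2 - sqrt(15) c4 + 2 sqrt(21) c6
    g0 = c0 - 2 sqrt(5) c4 + 5 sqrt(7) c6

The test suite re-derives both the modes and this matrix symbolically
(sympy) and verifies pointwise that both expansions reconstruct the same
polynomial.  The `g0` row fixes the piston convention implied by
`G0 = Z0`; piston never enters any reported delta or diopter value.  The
`-sqrt(15) c4` term in `g2` is the whole story of the Zernike defocus
artifact: one micron of Zernike primary SA hides 3.87 µm of quadratic
wavefront inside `Z4`.

## Wavefront deltas and diopters

Surface-coefficient changes become wavefront changes via the index step:
`dz_n = (c_n_post - c_n_pre) * 0.376`, and the LD/HD delta follows by
linearity of the conversion.  The spherical equivalent of a defocus
coefficient `c` (µm) over a zone `S` (mm) is `SE = 4 sqrt(3) c / (S/2)^2`,
signed so that positive SE means increased corneal power; the
subjective-refraction shift is `-SE`.  Deltas are computed
coefficient-wise (identical to subtracting absolute SEs, by linearity).

## Scenario engine

- **Spherical sweep** (conventional profiles, `Q0 = Q1 = 0`): corrections
  −10…+6 D in 1 D steps on `R0 = 7.8 mm`, 6 mm zone.  The apical radius
  behind the published sweep is not stated; 7.8 mm (the presbyopia-table
  value) reproduces the reported overshoots and is the package default,
  exposed as a parameter.
- **Zone sweep**: one correction analyzed for `S = 5.0…8.0 mm` in 0.5 mm
  steps.
- **Asphericity sweeps** (custom aspheric, `D = 0`): `Q` changed in 0.1
  steps at constant apical radius, on an oblate (`R0 = 8.5`, `Q0 = +0.5`)
  or hyperprolate (`R0 = 7.3`, `Q0 = -0.8`) cornea.
- **Presbyopia table**: hyperopic corrections +2/+4/+6 D on `R0 = 7.8`,
  `Q0 = -0.2` with the post-operative asphericity solved so that the
  fourth-order Zernike coefficient changes by −0.40 µm.

The `Q1` solver finds the root of
`f(Q1) = 0.376 (c4(R1, Q1) - c4(R0, Q0)) - dz4_target` with Brent's
method on the bracket `Q1 in [-3, +1]` (tolerance 1e-8 on `Q1`); `f` is
monotone increasing in `Q1`, and an unbracketable target fails loudly with
the offending parameters.  Solver iteration counts are logged at debug
level.

The ablation thickness profile (gap between the conics plus a centering
offset `t0` chosen so the minimum removal over the zone is exactly zero,
located on a 2049-point radial grid) is provided as a diagnostic; no
coefficient depends on it.

## Numerical and reporting choices

- Radii and zones in mm, sagitta internally in mm, µm only at the
  projection boundary; diopters always from radii in meters.
- 64 quadrature nodes everywhere (configurable); all outputs bit-stable.
- CSV output has a fixed column order, 4-decimal µm / 2-decimal diopter
  display rounding, and an optional full-precision mode; rounding is
  display-only.
- Config files are flat YAML with strict unknown-key rejection and
  physical-range validation (`R0 in [5,12]` mm, `S in [3,9]` mm,
  `Q in [-3,1]`).

## Known limitations

- Only rotationally symmetric modes (orders 0–6) are handled; coma,
  astigmatism and other azimuthal modes, which show analogous
  low/high-degree coupling, are out of scope, as is pupil rescaling of
  coefficients between zones and any RMS aggregation across mixed LD+HD
  sets (the bases are not mutually orthogonal).
- The order-6 scalar-product fit of an exact conic is not a polynomial
  identity.  Consequently the LD/HD defocus of a zero-diopter aspheric
  profile is null only to ~1e-2 µm (≤ 0.01 D on 6 mm) — clinically null,
  not floating-point zero — and the measured log-log growth of |dz4| and
  |dz6| across zone diameters is ~4.4 and ~6.6 rather than the leading
  exponents 4 and 6.  Both are properties of the model, not numerical
  error; tests assert the honest bounds.
- The simulation addresses the anterior corneal surface at the corneal
  plane only: no pupil-plane transfer, no internal optics, no image
  quality metrics.
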