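# cornealwave

Simulation of corneal wavefront changes after conventional and customized
aspheric excimer-laser ablations, expressed in two bases: the rotationally
symmetric Zernike modes and the low-degree/high-degree (LD/HD)
decomposition whose high-order modes contain no quadratic term.

It is written for visual-optics researchers and refractive-surgery
planners who need to understand — before any tissue is touched — how a
planned change of corneal apical radius and asphericity will read out in
wavefront coefficients, and why the Zernike defocus coefficient predicts
spurious refraction changes for purely aspheric (zero-diopter) profiles.

## Model

The anterior cornea is a conic section with apical radius `R` (mm) and
asphericity `Q`, with sagitta

    z(r) = r^2 / ( R (1 + sqrt(1 - (1+Q) r^2 / R^2)) ).

A planned correction of `D` diopters at the corneal plane maps `R0` to the
post-operative radius through the paraxial surface-power formula
`1/R1 = 1/R0 + D/(n'-1)` with the stromal index `n' = 1.376`.  Pre- and
post-operative surfaces are projected onto the rotationally symmetric
Zernike modes `Z0, Z2, Z4, Z6` over a zone of diameter `S` by scalar
products (Gauss–Legendre quadrature), and the wavefront change is

    dz_n = (c_n_post - c_n_pre) * (n' - 1).

The same change is re-expressed in the LD/HD basis `G0 = Z0`, `G2 = Z2`,
`G4 = sqrt(5) rho^4`, `G6 = sqrt(7)(6 rho^6 - 5 rho^4)` through the exact
linear map (derived at import time by monomial bookkeeping)

    g6 = (10/3) c6
    g4 = 6 c4 - (40/3) sqrt(7/5) c6
    g2 = c2 - sqrt(15) c4 + 2 sqrt(21) c6
    g0 = c0 - 2 sqrt(5) c4 + 5 sqrt(7) c6.

Dioptric summaries use the spherical equivalent
`SE = 4 sqrt(3) c2 / (S/2)^2` (c2 in µm, S/2 in mm; positive = more
corneal power) and the refraction shift `-SE`.

Because `Z4` and `Z6` embed `r^2` terms, the Zernike defocus coefficient
mixes paraxial power with spherical aberration; the HD modes are built
without low-degree monomials, so `g2` carries the paraxial curvature of
the fitted wavefront alone.  The scenarios quantify the practical
consequences.

## Worked example

```
python examples/presbyopia_table.py
```

prints (computed live; µm and diopters over a 6 mm zone):

```
     D      Q1     R1    dz2    dg2   SE_z   SE_g
 +2.00   -0.82   7.49   1.12   2.60  +0.86  +2.00
 +4.00   -0.84   7.20   3.72   5.19  +2.86  +4.00
 +6.00   -0.86   6.94   6.32   7.79  +4.86  +6.00
```

Each row is a presbyopic custom ablation on `R0 = 7.8 mm`, `Q0 = -0.2`:
the planned hyperopic correction `D` sets `R1`, and `Q1` is solved so the
fourth-order Zernike coefficient changes by exactly `-0.40 µm` (inducing
negative spherical aberration for depth of focus).  The spherical
equivalent computed from the LD/HD defocus change (`SE_g`) recovers the
plan; the one computed from the Zernike defocus change (`SE_z`)
underestimates it by about `1.14 D`, because the induced negative SA drags
`dz2` down through the `-sqrt(15) c4` coupling.  A surgeon reading only
Zernike coefficients would misjudge the refractive effect of the profile.

Other examples: `spherical_sweep.py` (conventional −10…+6 D corrections),
`asphericity_sweep.py` (zero-diopter custom profiles on an oblate cornea),
`basis_conversion.py` (the conversion algebra).  The same studies are
available from a shell:

```
cornealwave presbyopia-table --out table.csv
cornealwave asphericity-sweep --r0 8.5 --q0 0.5 --dq="-1.0:-0.1:0.1"
cornealwave convert --from-basis zernike -- 0 0 -0.4 0
```

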