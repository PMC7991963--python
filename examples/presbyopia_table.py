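"""Presbyopic custom ablations: hyperopic correction plus a fixed negative
spherical-aberration target.

For D = +2/+4/+6 D on a cornea with R0 = 7.8 mm and Q0 = -0.2 over a 6 mm
zone, the post-operative asphericity Q1 is solved so the fourth-order
Zernike wavefront coefficient changes by -0.40 um.  The table shows the
key discrepancy between the bases: the LD/HD defocus SE equals the plan,
while the Zernike defocus SE underestimates it by ~1.14 D because Z4
carries a quadratic term.
"""

from cornealwave import presbyopia_table

print(f"{'D':>6} {'Q1':>7} {'R1':>6} {'dz2':>6} {'dg2':>6} {'SE_z':>6} {'SE_g':>6}")
for res in presbyopia_table():
    d = res.delta
    print(
        f"{res.d:+6.2f} {res.q1:7.2f} {res.r1:6.2f} {d.dz.c2:6.2f} "
        f"{d.dg.g2:6.2f} {d.dse_zernike:+6.2f} {d.dse_ldhd:+6.2f}"
    )
print(
    "\nColumns: planned correction (D), solved asphericity Q1, postop apical"
    "\nradius (mm), defocus coefficient changes (um) and their spherical"
    "\nequivalents (D) in the Zernike vs LD/HD bases.  SE_g recovers the plan;"
    "\nSE_z is dragged down by the r^2 term inside the Z4 mode."
)
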