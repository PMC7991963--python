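"""Custom aspheric ablations that change only asphericity (D = 0).

An oblate post-myopic-LASIK cornea (R0 = 8.5 mm, Q0 = +0.5) is reshaped
toward prolateness in dQ = -0.1 steps with the apical radius untouched.
Ideally a zero-diopter plan changes no defocus; the sweep shows the
Zernike defocus coefficient moving by up to -2 um (a spurious +1.55 D
"hyperopic shift") while the LD/HD defocus stays at the milli-micron
level.
"""

import numpy as np

from cornealwave import ConicSurface, OpticalZone, run_asphericity_sweep

rows = run_asphericity_sweep(
    ConicSurface(8.5, 0.5), -np.arange(0.1, 1.01, 0.1), OpticalZone(6.0)
)
print(f"{'dQ':>6} {'dz2 (um)':>9} {'dg2 (um)':>9} {'shift_z (D)':>12}")
for r in rows:
    d = r.delta
    print(f"{r.dq:+6.1f} {d.dz.c2:9.4f} {d.dg.g2:9.4f} {d.shift_zernike:+12.2f}")
print(
    "\nWith zero planned defocus, the Zernike defocus change (dz2) only"
    "\nbalances the quadratic terms inside Z4/Z6 - an interpretation artifact."
    "\nThe LD/HD defocus (dg2) correctly stays null at clinical precision."
)
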