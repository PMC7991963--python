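"""Conventional spherical corrections from -10 D to +6 D (Q0 = Q1 = 0).

Both surfaces are spheres, so the only intended change is paraxial power.
The spherical equivalent computed from the LD/HD defocus coefficient
recovers the plan at every correction; the one computed from the Zernike
defocus coefficient overshoots it - by 1.0 D (myopic) at -10 D and 0.86 D
(hyperopic) at +6 D on a 6 mm zone.
"""

from cornealwave import OpticalZone, run_spherical_sweep

print(f"{'D':>6} {'SE_z (D)':>9} {'SE_g (D)':>9} {'excess_z':>9}")
for r in run_spherical_sweep(7.8, range(-10, 7), OpticalZone(6.0)):
    d = r.delta
    print(f"{r.d:+6.0f} {d.dse_zernike:+9.2f} {d.dse_ldhd:+9.2f} "
          f"{d.dse_zernike - r.d:+9.2f}")
print(
    "\nexcess_z is the amount by which the Zernike-derived SE exceeds the"
    "\nplanned correction; it grows with the correction magnitude because"
    "\nspherical ablations also change r^4/r^6 surface content, whose Zernike"
    "\nmodes feed back into the defocus coefficient."
)
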