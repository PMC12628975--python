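"""Correct an H+ flux for transport by the pH buffer.

In a Mes-buffered bath most of an acid flux travels as protonated buffer
(MesH) rather than free H+; the measured free-H+ flux must be scaled up to
recover the membrane flux.
"""

import ionflux as ifx

mes = ifx.lookup_buffer("Mes", solution_pH=6.1)
J_free = -1e-7  # mol m^-2 s^-1 of free H+, efflux-signed

print("chemical-potential route: J_total = (r + 1) J_H+")
for C_buf in (0.1, 1.0, 5.0):
    r = ifx.buffer_ratio(mes, C_buf, pH=6.1)
    total = ifx.correct_flux_chemical(J_free, r)
    print(f"  {C_buf:4.1f} mM Mes: r = {r:7.2f}, "
          f"J_total = {total * 1e9:9.1f} nmol m^-2 s^-1")

print("\nFick route: add the protonated-buffer Fick flux")
ha0 = ifx.protonated_conc(mes, 1.0, pH=6.05)
ha1 = ifx.protonated_conc(mes, 1.0, pH=6.15)
total = ifx.correct_flux_fick(J_free, mes, 1.0, pH0=6.05, pH1=6.15, dx=50e-6)
print(f"  [MesH] = {ha0:.4f} mM at position 0, {ha1:.4f} mM at position 1")
print(f"  J_total = {total * 1e9:.1f} nmol m^-2 s^-1 "
      f"(free H+ alone: {J_free * 1e9:.1f})")
print(
    "\nEven 1 mM of buffer carries an order of magnitude more acid than the "
    "free protons, which is why unbuffered or weakly buffered baths are "
    "preferred for H+ flux measurements."
)
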