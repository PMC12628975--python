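"""Compare the chemical-potential and diffusion-gradient flux estimates.

A strong K+ efflux lifts the concentration at the measurement positions to
~1.5 mM while the bath is 0.5 mM.  The bulk-referenced chemical-potential
method then underestimates the flux threefold; referencing it to the
measured position-1 concentration instead brings it back onto the Fick
estimate.
"""

import ionflux as ifx

ion = ifx.lookup_ion("K+")
geom = ifx.GeometrySpec(gap0=50e-6)
J_src = ifx.diffusion_coefficient(ion) * 1.0 / 425e-6  # ~4.5e-6 mol m^-2 s^-1

sc = ifx.SimulationScenario(
    ion=ion, bulk_conc=0.5, true_flux=J_src, geometry=geom,
    electrode=ifx.ElectrodeModel(tau=0.0, drift=0.0, noise_sd=0.0),
    n_loops=6, seed=0,
)
rec, truth = ifx.simulate(sc)
cal = ifx.fit_calibration([(0.1, -58.0), (1.0, 0.0), (10.0, 58.0)])

configs = {
    "chemical potential (bulk 0.5 mM)":
        ifx.FluxConfig("chemical_potential", ion, bath_conc=0.5, geometry=geom),
    "chemical potential (position-1 conc)":
        ifx.FluxConfig("chemical_potential", ion, bath_conc=0.5,
                       use_position1_conc=True, geometry=geom),
    "diffusion gradient (Fick)":
        ifx.FluxConfig("diffusion_gradient", ion, geometry=geom),
}
print(f"local concentration at the positions: "
      f"{truth.conc0[0]:.3f} / {truth.conc1[0]:.3f} mM (bath 0.5 mM)")
fluxes = {}
for label, cfg in configs.items():
    out = ifx.analyse(rec, cal, cfg, start_fit=5.0)
    fluxes[label] = out.table["flux1_nmol_m2_s"].mean()
    print(f"{label:40s} J = {fluxes[label]:9.1f} nmol m^-2 s^-1")

ratio = fluxes["diffusion gradient (Fick)"] / \
    fluxes["chemical potential (bulk 0.5 mM)"]
print(f"\nFick / bulk-referenced ratio: {ratio:.2f}")
print(
    "Negative fluxes denote efflux.  The bulk-referenced estimate is ~3x "
    "too small because the true local concentration is 3x the bath value; "
    "the position-1-corrected variant closes the gap."
)
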