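"""Show that the paired-regression dV estimate cancels electrode drift.

The same scenario is simulated without drift and with a hefty 5 mV/min
drift; the three-loop regression procedure returns the same dV either way.
"""

import ionflux as ifx

base = dict(
    ion=ifx.lookup_ion("K+"), bulk_conc=0.5, true_flux=2e-7,
    geometry=ifx.GeometrySpec(gap0=50e-6), n_loops=5, seed=0,
)
acq = ifx.AcquisitionConfig()

for drift in (0.0, 5.0):
    el = ifx.ElectrodeModel(tau=0.5, drift=drift, noise_sd=0.0)
    rec, truth = ifx.simulate(ifx.SimulationScenario(electrode=el, **base))
    segments = ifx.segment(rec, acq)
    dvs = [e.dV for e in ifx.dv_series(segments, start_fit=5.0)]
    print(f"drift {drift:4.1f} mV/min -> dV estimates (mV): "
          + ", ".join(f"{dv:.5f}" for dv in dvs))

print(f"ground-truth dV: {truth.true_dv_mV[1]:.5f} mV")
print(
    "\nThe raw voltage rises by 25 mV over this 50 s run in the drifted "
    "case, yet the drift-corrected dV estimates match the drift-free run "
    "and the ground truth: linear drift lives in the shared regression "
    "slope, not in the offset between the parallel lines."
)
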