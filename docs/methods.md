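# Methods

## The measurement model

A tissue exchanging an ion with the bath at surface flux J sustains a
steady-state diffusion profile in the unstirred layer next to it.  An
ion-selective electrode at distance x from the surface reads

V(x) = intercept + slope · log₁₀(c(x) / 1 mM),

and shuttling the electrode between two positions converts the concentration
difference into a voltage difference dV = V₀ − V₁.  The package's analysis
chain estimates dV robustly against sensor drift and converts it (or the
back-calculated concentrations) into J.

All concentrations cross module boundaries in mol m⁻³, which is numerically
equal to mM; user-facing tables display mM.  Fluxes are computed in
mol m⁻² s⁻¹ and written to analysis files in nmol m⁻² s⁻¹.

### Sign conventions

Two conventions coexist and are deliberately kept distinct:

- Analysis: J > 0 is influx into the tissue.  With dV = V₀ − V₁ and a
  non-inverting cation electrode, an efflux elevates c at position 0, so
  dV > 0 ⇒ J < 0.  The flip is applied once, inside the flux formulas.
- Simulator: the scenario's source flux is efflux-positive (it feeds the
  field), so a recovered analysis flux equals −true_flux.

The chemical-potential formula is implemented as
J = −C·u·((58/|z|)/slope_cal)·(dV/dx) with the *signed* calibration slope.
Writing |z| rather than z makes the expression consistent with the
Fick/Einstein identity for anions as well: for an anion both the ideal and
the fitted slope change sign, and the measured slope carries that sign into
the formula.  Any constant amplifier gain (including the common −33×
inverting low-pass stage) multiplies dV and slope_cal alike and cancels; a
property test pins this down to gain −33.

## Drift-corrected dV

For each interior loop i, one OLS line V = a + b·t is fitted through the
pooled samples of loops i−1 and i+1 (same position), and a second line with
the same slope b through loop i; dV is the vertical offset between the
lines, signed as V₀ − V₁.  The pooled outer fit (rather than averaging two
per-loop fits) is the package's reading of the procedure; the regression is
parameterised about the middle loop's midpoint for conditioning, which is
also where V₀/V₁ are evaluated (irrelevant under linear drift).  Only
samples past the start-fit time (default 5 s into each 10 s loop) enter any
fit, allowing the electrode's exponential response to settle: with a 0.5 s
time constant the residual at 5 s is e⁻¹⁰ ≈ 5·10⁻⁵ of the step.

Triples are skipped (with a logged reason) rather than failing the run when
the position pattern is broken, a loop is truncated, or a loop overlaps a
reposition event mark; truncated final loops are excluded from dV analysis
entirely.  Linear drift of any magnitude cancels to machine precision
(~10⁻¹² mV here); drift that is *curved* over the ~30 s window does not, and
no robust/weighted variant is provided — users exclude marked intervals
instead.

Note one asymmetry: the chemical-potential method uses only the slope of
the calibration and is therefore drift-insensitive, but the Fick method
back-calculates absolute concentrations through the intercept, so residual
drift biases its c₀, c₁ multiplicatively even though c₀ − c₁'s *relative*
error stays small.  This is inherent to the formalism, not an artefact.

## Physical constants

The ideal electrode slope is fixed at 58 mV per decade per unit valency
(the historical value, corresponding to ~18–19 °C); temperature is not a
parameter.  The diffusion coefficient is always derived from the tabulated
mobility via the Einstein relation D = u·V_T/|z| with V_T = 0.058/ln 10 V ≈
25.19 mV, so the two flux formalisms coincide exactly as the gradient
vanishes — a property the tests exercise at relative gradients 10⁻³–10⁻².

Ion mobilities ship as an editable TSV derived from CRC Handbook limiting
molar conductivities (u = λ⁰/(|z|F), 25 °C): H⁺ 36.23, K⁺ 7.62, Na⁺ 5.19,
NH₄⁺ 7.62, Ca²⁺ 6.17, Mg²⁺ 5.50, Cl⁻ 7.91, NO₃⁻ 7.40 (×10⁻⁸ m² V⁻¹ s⁻¹).
Buffer entries (Mes pK 6.10, TRIS pK 8.06, citrate pK 4.76, malate pK 5.13)
carry literature-estimate transport constants for the *protonated* species;
since the buffer formulas use only the ratio u_HA/u_H and D_HA linearly,
replacing these estimates rescales the correction without changing its
structure.  Polyprotic organic-acid buffers are tabulated with a single pK
and refused when the solution pH is more than 0.25 units from it, because
neighbouring dissociations would otherwise contribute.

## Geometry correction

Fluxes are referenced to the tissue surface.  For a cylinder or sphere of
radius a with the near position a gap g from the surface (r₀ = a + g,
r₁ = r₀ + d, d the surface-normal electrode displacement), the steady-state
profiles give effective distances dx = a·ln(r₁/r₀) and dx = a²(r₁−r₀)/(r₀r₁);
both converge to d as a → ∞.  A scan at angle θ from horizontal reduces the
normal displacement to d = scan_distance·cos θ; the recorded position column
always stores the full travel distance, and simulator and analyser apply the
same cosine, keeping the conventions aligned.

## The simulator

The synthetic field is the closed-form steady-state profile inside an
unstirred layer of thickness L (default 500 µm — a typical scale for a
quiescent bath; the exact value only sets the absolute concentration offset,
not the position-0/1 difference for flat geometry):

- flat c(x) = bulk + (J/D)(L − x); cylinder c(r) = bulk + (Ja/D)·ln(R/r);
  sphere c(r) = bulk + (Ja²/D)(1/r − 1/R), with R = a + L and c = bulk
  outside.

The field tracks a piecewise-constant source flux quasi-statically; the
transient re-equilibration of a real unstirred layer (and the convection
artefacts that follow solution changes) is not modelled — an event mark can
be injected where a user wants to emulate a disturbed interval.  The
electrode adds, in order: a first-order exponential lag (exact per-sample
update, default τ = 0.5 s), linear drift (mV/min), and i.i.d. Gaussian noise
(default 0.03 mV, the noise floor of a good A/D chain; real electrodes are
noisier).  Defaults elsewhere mirror the standard protocol: 10 ms sampling,
10 s loops of exactly 1000 samples, 50 µm scan, first loop stationary at
position 0.

What passing recovery tests therefore shows: the analysis inverts the
*model* — Nernstian sensor over a steady diffusion field with linear drift
and white noise — exactly or to the stated tolerances.  It does not certify
behaviour under convection, non-Nernstian interference (no
Nikolsky–Eisenman terms), activity-coefficient effects, electric fields in
the bath, or drift that curves within a 30 s window.

## Numerical and design choices

- Segmentation trusts the recorded position channel, not loop arithmetic
  (hardware may stretch loops); plateau levels must sit within ±10% of the
  scan distance, mid-travel samples join the following segment, and three or
  more consecutive intermediate samples are treated as a third level and
  rejected.
- Calibration is per channel (channel 2 needs its own curve), fitted with
  ordinary least squares on log₁₀(c); |slope| < 1 mV/decade is rejected as a
  dead electrode, and the CLI warns (not errors) at >20% deviation from the
  ideal 58/|z| — electrode quality is the experimenter's judgement.
- Buffer correction is restricted to H⁺ channels; the pH at each position is
  taken from the same channel's back-calculated concentrations
  (pH = 3 − log₁₀(c/mM)), and the chemical-potential route evaluates r at
  the mean of the two positions' pH.
- The recording dialect writes fixed decimals (10⁻⁵ s, 10⁻⁴ µm, 10⁻⁶ mV), so
  write→read→write is byte-identical and files diff cleanly; 10⁻⁶ mV is
  three orders below the best-case noise floor.
- The analysis table's 15-column maximum layout is fixed; absent optional
  columns are omitted, never blank-filled.
- Problem sizes in the test and acceptance runs (4–6 loops, i.e. 40–60 s of
  synthetic recording) are the smallest that exercise every code path —
  a dV estimate needs three loops — and keep the full suite under a few
  seconds; the estimators are per-triple, so nothing about them changes at
  experimental durations.

## Known limitations

- No conversion from the original acquisition software's native files; the
  ASCII dialect here is this package's own, designed to be easy to convert
  into.
- Chemical-potential fluxes for mixtures under applied electric fields
  (e.g. two-electrode voltage clamp) conflate electromigration of all ions;
  interpreting such recordings is out of scope.
- Mobilities are infinite-dilution values; no ionic-strength correction.
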