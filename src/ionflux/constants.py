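"""Fixed physical constants of the measurement model.

The electrode model uses the historical ideal Nernst slope of 58 mV per
decade for a monovalent ion (corresponding to roughly 18-19 degC);
temperature is deliberately not a parameter.  The same 58 mV constant,
divided by ln(10), is the thermal voltage used by the Einstein relation to
link ionic mobility to the diffusion coefficient, so the chemical-potential
and diffusion-gradient flux formalisms agree exactly in the small-gradient
limit.
"""

import math

#: Ideal slope of an ion-selective electrode, mV per decade, for |z| = 1.
#: The ideal slope for an ion of valency z is NERNST_SLOPE_IDEAL_MV / z.
NERNST_SLOPE_IDEAL_MV: float = 58.0

#: Thermal ("Einstein") voltage in volts: 0.058 V / ln(10) ~= 0.02519 V.
#: Links mobility to diffusivity via D = u * EINSTEIN_VOLTAGE / |z|.
EINSTEIN_VOLTAGE: float = NERNST_SLOPE_IDEAL_MV * 1e-3 / math.log(10.0)
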