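# pH-buffer table: name, pK of the relevant dissociation, mobility u_HA and
# diffusion coefficient D_HA of the protonated form, polyprotic flag.
# u_HA/D_HA are literature estimates for the neutral protonated species
# (see docs/methods.md); polyprotic organic acids list one pK and may only be
# used within 0.25 pH units of it.
# name	pK	u_HA	D_HA	polyprotic
Mes	6.10	2.54e-8	0.64e-9	no
TRIS	8.06	3.02e-8	0.76e-9	no
citrate	4.76	2.62e-8	0.66e-9	yes
malate	5.13	3.10e-8	0.78e-9	yes
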