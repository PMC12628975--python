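# Ion species table: name, signed valency z, limiting ionic mobility u (m^2 V^-1 s^-1).
# u derived from limiting molar conductivities (CRC Handbook, aqueous, 25 degC)
# via u = lambda0 / (|z| * F).  Edit or extend freely; the file is re-read on import.
# name	z	u
H+	1	36.23e-8
K+	1	7.62e-8
Na+	1	5.19e-8
NH4+	1	7.62e-8
Ca2+	2	6.17e-8
Mg2+	2	5.50e-8
Cl-	-1	7.91e-8
NO3-	-1	7.40e-8
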