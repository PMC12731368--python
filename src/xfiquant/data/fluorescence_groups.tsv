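# Shell-summed fluorescence production cross-sections (cm^2 per g of element),
# modelled as sigma(E) = sigma_ref * (e_ref / E)^exponent for E above edge_keV.
# edge_keV is the highest subshell edge of the shell (full shell excitable).
# sigma_ref is the summed production cross-section of all tabulated lines of the
# shell at e_ref; per-line values follow the emission_lines branching fractions.
# element	shell	edge_keV	e_ref_keV	sigma_ref_cm2_g	exponent
Au	L	14.353	53.0	0.89	2.70
W	L	12.100	53.0	0.80	2.70
Ta	L	11.682	53.0	0.77	2.70
Sr	K	16.105	53.0	0.70	2.75
Rb	K	15.200	53.0	0.62	2.75
Zn	K	9.659	53.0	0.27	2.80
Ni	K	8.333	53.0	0.20	2.80
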