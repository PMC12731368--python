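# Characteristic X-ray emission lines (Siegbahn labels, ASCII).
# group = fine-structure subgroup used for tied-area fitting; rel_intensity is
# relative to the strongest line of the same shell (La1 / Ka1 = 1).
# element	line	group	shell	energy_keV	rel_intensity
Au	Ll	La	L	8.494	0.043
Au	La2	La	L	9.628	0.114
Au	La1	La	L	9.713	1.000
Au	Lb1	Lb	L	11.442	0.670
Au	Lb2	Lb	L	11.585	0.230
Au	Lg1	Lg	L	13.382	0.130
W	Ll	La	L	7.387	0.040
W	La2	La	L	8.335	0.113
W	La1	La	L	8.398	1.000
W	Lb1	Lb	L	9.672	0.600
W	Lb2	Lb	L	9.961	0.210
W	Lg1	Lg	L	11.286	0.120
Ta	La2	La	L	8.088	0.113
Ta	La1	La	L	8.146	1.000
Ta	Lb1	Lb	L	9.343	0.590
Ta	Lb2	Lb	L	9.651	0.200
Ta	Lg1	Lg	L	10.895	0.110
Sr	Ka2	Ka	K	14.098	0.520
Sr	Ka1	Ka	K	14.165	1.000
Sr	Kb1	Kb	K	15.836	0.190
Rb	Ka2	Ka	K	13.336	0.520
Rb	Ka1	Ka	K	13.395	1.000
Rb	Kb1	Kb	K	14.961	0.180
Zn	Ka2	Ka	K	8.616	0.510
Zn	Ka1	Ka	K	8.639	1.000
Zn	Kb1	Kb	K	9.572	0.140
Ni	Ka2	Ka	K	7.461	0.510
Ni	Ka1	Ka	K	7.478	1.000
Ni	Kb1	Kb	K	8.265	0.140
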