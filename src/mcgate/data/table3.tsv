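# Intersegment contact energies (kcal/mol) of the R518H substitution in the
# inactivated (i), open (o) and closed (c) state models (Ia lineage), for the
# three histidine tautomers: HD1 (H on N-delta1), HE2 (H on N-epsilon2) and
# HIP (doubly protonated).  Verbatim transcription, blanks preserved.
# Residue numbers prefixed "b" belong to the beta subunit ("B 299" printed
# as-is in the source for D-beta-299).
residue	number	HD1_i	HD1_o	HD1_c	HE2_i	HE2_o	HE2_c	HIP_i	HIP_o	HIP_c
Y	576	-0.45	-0.47						-0.31
S	577	-2.7	-2.28	-1.20	-2.26	-2.73	-1.45	-3.31	-1.51	-1.37
L	578	-0.62			-0.34			-0.90
D	339							-0.86	-1.37	-1.46
Q	443	-0.54	-1.18	-1.95	-0.81	-1.52	-1.56	-0.99	-2.65	-1.55
D	446							-0.57	-0.83	-1.24
I	447		-0.64	-1.64		-0.59	0.71		-0.58	-1.16
R	4562		-0.47							0.35
K	2554									0.45
K	b295							0.40	0.48
D	b299							-0.45	-0.44
F	b300		-0.88		-1.25	-0.61		-0.91	-1.23
Q	b438			-1.13			-1.61			-1.55
E	b440	-0.72	-1.90	-3.48	-0.88	-2.23	-3.05	-3.94	-6.70	-7.74
D	b441								-0.33	-0.73
E	b444							-0.54		-0.44
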