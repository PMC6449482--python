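# Intersegment contact energies (kcal/mol) of the G402S and G406R
# substitutions in the closed (c) and open (o) state models (Ia lineage).
# Verbatim transcription of the printed table, blanks preserved.
# Annotations:
#  - The printed SUM for G406R/o is -4.98, but the printed column entries
#    sum to -4.89; transcribed verbatim, not reconciled.
#  - Rows "I 261 1k11" and "K 261 1o1" both print residue number 261 in the
#    source; the label map implies K271 for 1o1.  Transcribed verbatim.
#  - "A 262 1o2" appears twice in the source (open and closed rows).
residue	number	label	G402S_c	G402S_o	G406R_c	G406R_o
I	261	1k11				-2.27
S	260	1k10				-1.38
A	262	1o2		-1.05		-0.63
N	746	2i20				-0.56
V	257	1k7				-0.38
L	269	1o6		-0.82
P	267	1o5		-0.85	-0.56
K	261	1o1			0.35	0.33
A	262	1o2			-0.30
L	1397	4k7			-0.30
F	1401	4k11	-0.75
SUM			-0.75	-2.72	-0.81	-4.98
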