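# Intersegment contact energies (kcal/mol) of the R518C substitution in the
# inactivated (i), open (o) and closed (c) state models, for the reduced
# cysteines and the vicinal-disulfide form, in both template lineages
# (Ia and II).  Verbatim transcription of the printed main entries; the
# source also prints parenthesized wild-type comparison values on
# continuation lines whose column alignment is ambiguous in the extracted
# text -- they are preserved below as raw annotation lines.
residue	number	red_Ia_i	red_Ia_o	red_Ia_c	red_II_i	red_II_o	red_II_c	ss_Ia_i	ss_Ia_o	ss_Ia_c	ss_II_i	ss_II_o	ss_II_c
S	577	-0.86	-0.58	-0.80				-0.27	-0.84	-0.70
L	578					-0.47		-0.13			-0.34	-0.45
D	439
Q	443	-0.26	-0.38	-0.62		-0.37		-0.41	-0.87	-0.27		-0.28	-0.3
D	446			-0.35
I	447		-0.27	-0.61						-0.41
F	b300	-0.36	-0.26					-0.98	-0.42
E	b440	-0.50	-1.06	-2.21				-1.67	-1.20	-1.98
# wt-annotation	D 439:	(-6.5)	(-6.7)	(-3.4)
# wt-annotation	Q 443:	(-1.5)	(-1.7)	(-2.6)	(-2.0)		(-3.6)
# wt-annotation	D 446:	(-6.1)				(-6.2)	(-5.1)
# wt-annotation	I 447:	(-1.4)		(-0.7)		(-0.6)	(-1.2)
# wt-annotation	F b300:	(-1.1)
# wt-annotation	E b440:	(-4.2)
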