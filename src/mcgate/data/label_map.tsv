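# Universal P-loop channel residue nomenclature for the hCav1.2 alpha-1 subunit.
# Segment codes: k = S4-S5 linker, o = S5, p = P1, i = S6.
# resid(repeat, seg, index) = anchor_resid + (index - origin_index).
# Anchors derived from in-text worked pairs (G402=1i24, R406=1i28, L276=1o6,
# A272=1o2, V257=1k7, I261=1k11, S260=1k10, F1401=4k11, L1397=4k7, N746=2i20);
# rows with provisional=1 lack an in-text anchor and are plausible
# reconstructions only.  The printed conflict "R406/1i24" (vs "R406/1i28")
# is resolved in favour of the self-consistent assignment G402=1i24.
repeat	segment	origin_index	anchor_resid	provisional
1	k	7	257	0
1	o	2	272	0
1	p	38	315	1
1	i	24	402	0
2	k	7	689	1
2	o	1	697	1
2	p	38	723	1
2	i	20	746	0
3	k	7	1068	1
3	o	1	1076	1
3	p	38	1114	1
3	i	24	1145	1
4	k	11	1401	0
4	o	1	1406	1
4	p	38	1444	1
4	i	24	1476	1
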