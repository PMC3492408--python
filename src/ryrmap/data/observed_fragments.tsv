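# Observed proteolytic fragments of the RyR1 photoaffinity-labeling experiment.
# apparent_kda: SDS-PAGE mobility estimate. nterm_read: Edman read, with
# '(A)' = low-confidence call, 'X' = unidentified cycle, '-' = skipped cycle,
# 'ND' = not determined (N-terminal blockage). start/end: assigned span in the
# parent protein (1-based inclusive); empty where unknown. calc_kda: average
# mass of the assigned span rounded to integer kDa. labeled: crosslinked by the
# photo-reactive ATP analog (streptavidin-detected). parent_id: proteolytic
# precursor fragment, where known. Fragments 2, 9, 12 and 14 were seen only in
# total-protein stain (unlabeled); 12 and 14 have no printed spans.
fragment_id	apparent_kda	nterm_read	start	end	calc_kda	protein	labeled	parent_id
1	170	TQVKGVGQN	3120	4673	176	RyR1	1
3	145	ND	1	1302	148	RyR1	1
6	110	AVVAXFRMTP	3631	4673	118	RyR1	1	1
7	102	ISHTDLVIG	1509	2399	102	RyR1	1
8	95	GSGPPAGPAL	427	1302	99	RyR1	1	3
11	70	KLGVDGEEEE	4476	5037	64	RyR1	1
15	45	RREHFGEEPP	2402	2795	45	RyR1	1
2			3120	4475		RyR1	0	1
9			3631	4475		RyR1	0	2
12			 	 		RyR1	0	7
14			 	 		RyR1	0	7
SERCA	50	AAVGNKMFVK	506	923	48	SERCA	1
CSQ	53	(E)GLDFPEYD(G)	30	395	41	CSQ	1
X	30	I(G)(F)(F)(L)(V)-(I)(E)(Y)				unknown	1
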