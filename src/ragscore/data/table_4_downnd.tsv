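s_no	symbol	name	pattern_score	status_score	cumulative_score
1	E2F2	E2F transcription factor 2	2	12	14
2	CDC45L	cell division cycle 45 homolog L	2	12	14
3	BMP7	bone morphogenetic protein 7	2	12	14
4	KCNG1	potassium voltage gated channel, subfamily G, member 1	2	12	14
5	S100Z	S100 calcium binding protein Z	2	12	14
6	EFNA2	ephrin A2	2	12	14
7	S100A2	S100 calcium binding protein A2	2	12	14
8	S100G	S100 calcium binding protein G	2	12	14
9	PLA1A	phospholipase A1 member A	2	12	14
10	S100A5	S100 calcium binding protein A5	2	12	14
11	S100B	S100 calcium binding protein B	2	12	14
12	EPHB3	EPH receptor B3	4	8	12
13	TRH	thyrotropin releasing hormone	2	10	12
14	FOXM1	forkhead box M1	2	10	12
15	S100A7A	S100 calcium binding protein A7A	2	10	12
16	S100A7	S100 calcium binding protein A7	2	10	12
17	GJB6	gap junction protein, beta 6, 30kDa	2	10	12
18	TACC3	transforming, acidic coiled coil containing protein 3	2	8	10
19	CDC20	cell division cycle 20 homolog (S. cerevisiae)	4	4	8
20	PTTG1	pituitary tumor transforming 1; pituitary tumor transforming 2	4	4	8
21	KIF20A	kinesin family member 20A	2	4	6
22	PAQR4	progestin and adipoQ receptor family member IV	2	4	6
23	CALB2	calbindin 2	2	4	6
24	CENPE	centromere protein E, 312kDa	2	4	6
25	GALNT12	UDP N acetyl alpha D galactosamine:polypeptide N acetylgalactosaminyltransferase 12 (GalNAc T12)	2	4	6
26	CENPA	centromere protein A	2	2	4
27	SLC26A4	solute carrier family 26, member 4	2	2	4
28	GREM2	gremlin 2, cysteine knot superfamily, homolog (Xenopus laevis)	2	2	4
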