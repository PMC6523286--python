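chrom	pos	gene	context
6	72952463
6	72964379
15	111194
15	29973349
16	33566554	PPP2CB	3UTR
16	33566935	PPP2CB	3UTR
17	64209287
19	20034966
19	20040153
19	20052361
19	20062503
19	20072295
19	20100030
19	20114792
19	20130159
19	20152245
19	20172164
19	20245553
19	20256174
19	20286580
19	20292945
19	20303661
19	20309777
19	20310190
19	20314276
20	21870155	MITF	exonic
20	21870230	MITF	exonic
20	21870310	MITF	exonic
20	21870623	MITF	3UTR
20	21871904	MITF	3UTR
20	21872335	MITF	3UTR
20	21872815	MITF	3UTR
20	21873532	MITF	3UTR
27	42911747	WNK1	exonic
27	42911917	WNK1	exonic
32	38734101
32	38767343
32	38788489
32	38789367
X	6604781	SHROOM2	exonic
X	6621021	SHROOM2	intronic
X	6628533	SHROOM2	intronic
X	6634742	SHROOM2	intronic
X	10131021	TRAPPC2	exonic
X	10175834	OFD1	exonic
X	35604689	USP9X/Y	exonic
X	57139861
X	60395963	PGK1
Y	26641
Y	316950
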