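chrom	start	end	cpgs	p_value	mean_0h	mean_24h	mean_48h	gene_id	functional_category	reported_pattern
16	2880299	2880358	3	0.042	31	37	27	ZG16B	Cell Migration	transient hypermethylation
X	55026095	55026179	3	0.014	26	35	38	APEX2	DNA Repair	early hypermethylation
5	40909532	40909656	1	0.009	28	38	20	C7	Immune	transient hypermethylation
2	98329337	98329462	3	0.042	25	34	37	ZAP70	Immune	early hypermethylation
8	16425403	16425502	1	0.033	57	47	38	MSR1	Immune	continuous hypomethylation
9	130700685	130700757	6	0.001	74	85	85	DPM2	Metabolism	early hypermethylation
19	35939798	35939864	3	0.015	29	36	23	FFAR2	Metabolism	transient hypermethylation
X	153743994	153744125	7	0.04	26	30	36	FAM3A	Metabolism	continuous hypermethylation
X	46433376	46433503	18	0.029	42	30	36	CHST7	Metabolism	early hypomethylation
X	128977778	128977938	12	0.003	26	36	40	ZDHHC9	Protein Modification	early hypermethylation
X	150863035	150863196	7	0.046	56	68	66	PRRG3	Protein Modification	early hypermethylation
22	51172813	51172946	4	0.014	61	73	70	ACR	Reproduction	early hypermethylation
X	134655182	134655341	14	0.046	40	36	28	DDX26B	RNA processing	late hypomethylation
16	2322947	2323056	4	0.046	57	64	69	RNPS1	RNA processing	continuous hypermethylation
5	180554560	180554676	1	0.003	84	88	96	OR2V1	Sensory Perception	continuous hypermethylation
20	62738880	62738959	4	0.004	16	23	12	NPBWR2	Signal Transduction	transient hypermethylation
20	57090702	57090793	2	0.025	23	17	30	APCDD1L	Signal Transduction	transient hypomethylation
X	63425502	63425652	11	0.041	31	29	42	FAM123B	Signal Transduction	transient hypomethylation
19	42760491	42760639	3	0.00003	46	52	62	ERF	Transcription	continuous hypermethylation
20	48805866	48805958	1	0.014	79	75	92	CEBPB	Transcription	late hypermethylation
16	30597821	30597994	7	0.025	39	43	53	ZNF785	Transcription	continuous hypermethylation
19	58571275	58571401	5	0.027	30	34	41	ZNF135	Transcription	continuous hypermethylation
20	61005667	61005710	1	0.0008	74	86	69	C20orf151	Unknown	transient hypermethylation
X	153233106	153233193	3	0.030	48	45	56	TMEM187	Unknown	late hypermethylation
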