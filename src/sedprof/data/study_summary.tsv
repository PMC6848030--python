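sample_id	assembly_size_mbp	cds_count_millions	egs_mbp	pct_tax_annotated	pct_bacteria	pct_archaea	pct_viruses	pct_bacillariophyta	pct_other_euk	genome_equivalents
S.41_BBB	1382	2.3	3.23	74.02	92.92	6.47	0.08	0.01	0.53	292
S.184_BBB	529	1.1	2.55	72.73	93.01	4.61	0.58	0.56	1.25	139
S.182_BBI	786	1.5	2.29	57.21	74.8	5.08	0.64	15.49	3.98	146
S.186_BBA	671	1.2	2.35	50.67	65.73	1.66	0.52	26.06	6.04	94
S.180_BBC	520	1.1	2.35	61.46	78.97	2.53	0.48	14.78	3.24	107
S.43_YBM	1099	2.0	2.94	74.27	97.68	0.85	0.16	0.15	1.16	268
S.178_YBM	934	1.9	2.94	66.51	91.71	2.64	0.18	3.1	2.37	192
S.42_YBB	1845	3.2	3.54	76.51	96.99	2.12	0.05	0.01	0.84	383
S.188_CBA	640	1.4	2.47	77.13	97.52	0.81	0.38	0.22	1.06	193
S.190_CBC	880	1.7	3.09	77.63	96.69	2.34	0.05	0.18	0.73	212
S.174_CBK	1210	2.4	3.15	80.05	97.82	1.37	0.07	0.28	0.46	298
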