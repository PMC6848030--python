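sample_id	bay	collection_date	ph	pct_om	no3_ppm	nh4_ppm	mn_ppm	fe_ppm
S.41_BBB	Baker	2011-08-22	7.5	1.8	8.1	2	15.5	20
S.184_BBB	Baker	2013-08-23	7.2	2.9	5	28	65	159
S.182_BBI	Baker	2013-08-23	7.5	0.7	3	14	28	70
S.186_BBA	Baker	2013-08-23	7.7	0.5	3	13	17	60
S.180_BBC	Baker	2013-08-23	7.5	0.6	3	15	19	45
S.43_YBM	Youngs	2011-08-22	6.6	5.4	3	150	243	214
S.178_YBM	Youngs	2013-08-23	7.2	1.1	3	8	25	131
S.42_YBB	Youngs	2011-08-22	6.3	8.8	2.5	170	162	254
S.188_CBA	Cathlamet	2013-08-23	6.9	2	6	44	89	140
S.190_CBC	Cathlamet	2013-08-23	6.7	2.3	4	22	48	97
S.174_CBK	Cathlamet	2013-08-19	7.4	0.7	3	14	46	75
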