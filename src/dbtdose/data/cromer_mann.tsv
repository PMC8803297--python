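# element	Z	A	a1	a2	a3	a4	b1	b2	b3	b4	c
H	1	1.008	0.489918	0.262003	0.196767	0.049879	20.6593	7.74039	49.5519	2.20159	0.001305
Be	4	9.0122	1.5919	1.1278	0.5391	0.7029	43.6427	1.8623	103.483	0.542	0.0385
C	6	12.011	2.31	1.02	1.5886	0.865	20.8439	10.2075	0.5687	51.6512	0.2156
N	7	14.007	12.2126	3.1322	2.0125	1.1663	0.0057	9.8933	28.9975	0.5826	-11.529
O	8	15.999	3.0485	2.2868	1.5463	0.867	13.2771	5.7011	0.3239	32.9089	0.2508
Al	13	26.9815	6.4202	1.9002	1.5936	1.9646	3.0387	0.7426	31.5472	85.0886	1.1151
Ar	18	39.948	7.4845	6.7723	0.6539	1.6442	0.9072	14.8407	43.8983	33.3929	1.4445
Rh	45	102.9055	19.2957	14.3501	4.73425	1.28918	0.751536	8.21758	25.8749	98.6062	5.328
W	74	183.84	29.0818	15.43	14.4327	5.11982	1.72029	9.2259	0.321703	57.056	9.8875
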