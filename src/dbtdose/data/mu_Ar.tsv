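# energy_keV	mu_total	mu_pe	mu_incoh	mu_coh	mu_en
1	3184	3180.95	0.0103546	3.04133	3183.68
1.2	1946.3	1943.32	0.0144211	2.95938	1946.1
1.4	1291.72	1288.83	0.018898	2.86899	1291.59
1.6	913.481	910.684	0.0236667	2.77255	913.389
1.8	679.264	676.563	0.0286156	2.67229	679.196
2	526	523.396	0.0336446	2.57022	525.947
2.2	420.913	418.406	0.038668	2.46807	420.871
2.4	345.485	343.074	0.0436156	2.36728	345.429
2.6	289.222	286.905	0.0484323	2.26896	288.874
2.8	245.934	243.707	0.0530771	2.17396	245.38
3	211.775	209.635	0.0575217	2.08286	211.074
3.2	184.248	182.19	0.061748	1.99604	183.441
3.2029	183.889	181.832	0.0618077	1.99482	183.08
3.2031	1275.91	1273.85	0.0618118	1.99473	1156.85
3.4	1097.26	1095.28	0.065747	1.91371	1000.94
3.6	949.386	947.481	0.0695159	1.83594	870.767
3.8	827.534	825.698	0.0730573	1.76268	762.661
4	726	724.23	0.0763774	1.69382	671.953
4.2	640.56	638.851	0.079485	1.62919	595.142
4.4	568.016	566.365	0.0823905	1.5686	529.553
4.6	505.929	504.332	0.0851055	1.51182	473.128
4.8	452.415	450.869	0.0876419	1.45861	424.264
5	406	404.501	0.0900117	1.40873	381.699
5.2	365.535	364.081	0.0922268	1.36196	344.442
5.4	330.164	328.751	0.0942988	1.31806	311.759
5.6	299.175	297.802	0.0962388	1.27681	283.032
5.8	271.96	270.624	0.0980573	1.23799	257.73
6	248	246.699	0.0997641	1.20142	235.393
6.2	226.846	225.578	0.101369	1.16691	215.623
6.4	208.103	206.865	0.102879	1.13428	198.066
6.6	191.435	190.227	0.104304	1.10338	182.421
6.8	176.562	175.382	0.10565	1.07405	168.432
7	163.247	162.094	0.106924	1.04617	155.886
7.2	151.291	150.164	0.108132	1.01962	144.601
7.4	140.524	139.42	0.10928	0.994272	134.421
7.6	130.799	129.719	0.110372	0.970041	125.214
7.8	121.994	120.935	0.111413	0.946832	116.865
8	114	112.963	0.112407	0.924563	109.275
8.2	106.724	105.708	0.113358	0.903163	102.33
8.4	100.081	99.0842	0.114268	0.882567	95.9827
8.6	93.9953	93.0175	0.115141	0.862715	90.1631
8.8	88.404	87.4444	0.115979	0.843557	84.8119
9	83.2526	82.3108	0.116785	0.825045	79.878
9.2	78.4945	77.5698	0.117561	0.807139	75.3175
9.4	74.0892	73.1811	0.118308	0.789801	71.0922
9.6	70.0015	69.1095	0.119028	0.772997	67.1691
9.8	66.2007	65.3243	0.119722	0.756699	63.5191
10	62.66	61.7987	0.120393	0.74088	60.117
10.5	54.8039	53.9787	0.121972	0.703271	52.5988
11	48.1612	47.3696	0.123424	0.668188	46.23
11.5	42.5167	41.7565	0.124763	0.63538	40.8098
12	37.6974	36.9667	0.125997	0.604642	36.1758
12.5	33.5635	32.8606	0.127137	0.575805	32.1964
13	30.0018	29.3249	0.128189	0.548727	28.7644
13.5	26.9198	26.2673	0.129161	0.523283	25.7922
14	24.2418	23.6124	0.130057	0.499363	23.2079
14.5	21.9057	21.2979	0.130883	0.476869	20.9523
15	19.86	19.2726	0.131643	0.45571	18.9762
15.5	18.062	17.4938	0.132342	0.435804	17.2326
16	16.4754	15.9254	0.132985	0.417072	15.6941
16.5	15.0702	14.5372	0.133574	0.399443	14.3317
17	13.8211	13.3042	0.134113	0.382846	13.1209
17.5	12.7072	12.2054	0.134606	0.367218	12.0414
18	11.7106	11.2231	0.135055	0.352497	11.0759
18.5	10.8164	10.3423	0.135464	0.338626	10.2098
19	10.0117	9.55035	0.135835	0.32555	9.43068
19.5	9.28572	8.83633	0.136171	0.313218	8.72802
20	8.629	8.19095	0.136474	0.301581	8.09267
20.5	8.03378	7.60617	0.137008	0.290594	7.51789
21	7.4928	7.07508	0.137508	0.280214	6.99565
21.5	7.00003	6.59165	0.137977	0.270402	6.52008
22	6.55021	6.15067	0.138416	0.26112	6.0861
22.5	6.13875	5.74759	0.138827	0.252334	5.68927
23	5.76165	5.37843	0.139212	0.244011	5.32571
23.5	5.4154	5.03971	0.139572	0.236122	4.99202
24	5.09691	4.72836	0.13991	0.228637	4.68521
24.5	4.80345	4.4417	0.140225	0.221531	4.40262
25	4.53262	4.17732	0.14052	0.214785	4.14194
25.5	4.28232	3.93311	0.140794	0.208412	3.90109
26	4.05064	3.70721	0.141048	0.202387	3.67822
26.5	3.83589	3.49792	0.141284	0.196682	3.47171
27	3.63654	3.30377	0.141503	0.191269	3.28009
27.5	3.45124	3.12341	0.141706	0.186124	3.10204
28	3.27877	2.95565	0.141895	0.181229	2.9364
28.5	3.11805	2.79942	0.14207	0.176564	2.78211
29	2.96809	2.65374	0.142232	0.172114	2.63822
29.5	2.82801	2.51776	0.142382	0.167864	2.50389
30	2.697	2.39068	0.142521	0.163801	2.37832
30.5	2.57424	2.27179	0.14253	0.159913	2.26083
31	2.45919	2.16046	0.142532	0.15619	2.15079
31.5	2.35127	2.05612	0.142526	0.152621	2.04763
32	2.24994	1.95823	0.142512	0.149198	1.95086
32.5	2.15473	1.86633	0.142492	0.145912	1.85998
33	2.06518	1.77996	0.142466	0.142756	1.77457
33.5	1.98088	1.69873	0.142433	0.139723	1.69424
34	1.90147	1.62227	0.142395	0.136806	1.61861
34.5	1.82659	1.55024	0.142352	0.134	1.54737
35	1.75594	1.48234	0.142303	0.131298	1.4802
35.5	1.68922	1.41828	0.14225	0.128696	1.41683
36	1.62617	1.35779	0.142192	0.126189	1.35699
36.5	1.56654	1.30064	0.14213	0.123771	1.30045
37	1.51011	1.24661	0.142064	0.121439	1.247
37.5	1.45667	1.19549	0.141994	0.119189	1.19642
38	1.40602	1.14708	0.14192	0.117017	1.14853
38.5	1.35799	1.10123	0.141843	0.114919	1.10315
39	1.31241	1.05775	0.141763	0.112892	1.06014
39.5	1.26913	1.01651	0.141679	0.110933	1.01934
40	1.228	0.977368	0.141593	0.109039	0.980606
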