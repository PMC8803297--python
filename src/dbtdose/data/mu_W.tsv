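# energy_keV	mu_total	mu_pe	mu_incoh	mu_coh	mu_en
1	47223.3	47211.8	0.00648393	11.4508	47211.8
1.2	28869	28857.7	0.0088971	11.2706	28857.7
1.4	19044	19032.9	0.0115261	11.0739	19032.9
1.6	13282.6	13271.7	0.0143013	10.8659	13271.7
1.8	9667.07	9656.4	0.0171633	10.651	9656.4
2	7276.03	7265.57	0.0200645	10.4328	7265.57
2.2	5627.3	5617.07	0.0229693	10.2139	5617.07
2.4	4451.02	4441	0.0258527	9.99624	4441
2.6	3587.67	3577.86	0.0286986	9.78097	3577.86
2.8	2938.63	2929.03	0.0314977	9.56884	2929.03
3	2440.61	2431.22	0.034245	9.36021	2431.22
3.2	2051.62	2042.42	0.0369385	9.15526	2042.42
3.4	1743.03	1734.03	0.0395776	8.95404	1734.04
3.6	1494.85	1486.05	0.0421624	8.75657	1486.05
3.8	1292.82	1284.21	0.0446927	8.56286	1284.21
4	1126.54	1118.12	0.0471684	8.37293	1118.12
4.2	988.353	980.117	0.0495889	8.18685	980.117
4.4	872.484	864.428	0.0519534	8.00469	864.428
4.6	774.544	766.663	0.0542611	7.82652	766.664
4.8	691.148	683.439	0.0565112	7.65242	683.439
5	619.655	612.113	0.0587028	7.48246	612.114
5.2	557.985	550.607	0.0608356	7.3167	550.608
5.4	504.483	497.265	0.0629094	7.15515	497.265
5.6	457.821	450.758	0.0649241	6.99784	450.758
5.8	416.922	410.011	0.0668802	6.84474	410.012
6	380.912	374.147	0.0687783	6.69582	374.148
6.2	349.069	342.447	0.0706194	6.55103	342.448
6.4	320.798	314.315	0.0724045	6.41029	314.316
6.6	295.604	289.256	0.0741349	6.27351	289.257
6.8	273.072	266.856	0.075812	6.1406	266.857
7	252.855	246.766	0.0774374	6.01146	246.768
7.2	234.658	228.693	0.0790127	5.88596	228.694
7.4	218.23	212.386	0.0805394	5.764	212.387
7.6	203.358	197.631	0.0820194	5.64546	197.632
7.8	189.859	184.245	0.0834541	5.53022	184.246
8	177.574	172.071	0.0848452	5.41817	172.072
8.2	166.369	160.973	0.0861943	5.30919	160.975
8.4	156.124	150.833	0.0875028	5.20318	150.835
8.6	146.737	141.548	0.0887724	5.10003	141.55
8.8	138.119	133.029	0.0900043	4.99963	133.031
9	130.191	125.198	0.0911998	4.9019	125.199
9.2	122.883	117.984	0.0923604	4.80675	117.986
9.4	116.136	111.328	0.093487	4.71408	111.33
9.6	109.895	105.176	0.0945809	4.62382	105.178
9.8	104.113	99.4811	0.0956432	4.53589	99.4828
10	98.7469	94.2	0.0966748	4.45022	94.2018
10.2067	93.5992	89.1375	0.0977098	4.36398	89.1394
10.2069	226.456	221.994	0.0977108	4.3639	200.621
10.5	210.585	206.24	0.0991259	4.24549	186.938
11	186.9	182.745	0.101405	4.05347	166.419
11.5	166.776	162.799	0.103524	3.87332	148.888
11.5439	165.156	161.194	0.103703	3.85804	147.473
11.5441	229.957	225.995	0.103704	3.85797	195.364
12	208.155	204.345	0.105494	3.70425	177.701
12.0997	203.773	199.996	0.10587	3.6718	174.134
12.0999	242.772	238.995	0.105871	3.67173	200.581
12.5	223.264	219.612	0.107325	3.54556	185.443
13	201.827	198.321	0.109027	3.39658	168.652
13.5	183.152	179.785	0.110607	3.2567	153.886
14	166.802	163.564	0.112074	3.12533	140.844
14.5	152.417	149.302	0.113436	3.0019	129.278
15	139.705	136.705	0.114701	2.8859	118.982
15.5	128.426	125.533	0.115874	2.7768	109.784
16	118.378	115.587	0.116963	2.67414	101.54
16.5	109.395	106.7	0.117973	2.57747	94.1258
17	101.336	98.7311	0.118911	2.48636	87.439
17.5	94.0837	91.5635	0.119781	2.40041	81.3909
18	87.5365	85.0967	0.120589	2.31926	75.9057
18.5	81.6094	79.2455	0.121339	2.24255	70.9183
19	76.229	73.937	0.122036	2.16998	66.3725
19.5	71.3324	69.1085	0.122683	2.10125	62.2198
20	66.8652	64.7058	0.123284	2.03608	58.4177
20.5	62.7802	60.6822	0.123842	1.97422	54.9295
21	59.0367	56.9969	0.124361	1.91544	51.7227
21.5	55.5988	53.6144	0.124843	1.85954	48.769
22	52.4352	50.5036	0.125291	1.80631	46.0436
22.5	49.5185	47.6372	0.125707	1.75557	43.5244
23	46.8246	44.9913	0.126093	1.70718	41.1919
23.5	44.332	42.5446	0.126451	1.66096	39.0287
24	42.022	40.2784	0.126783	1.61679	37.0196
24.5	39.8775	38.1759	0.127092	1.57455	35.1508
25	37.8839	36.2224	0.127376	1.53417	33.41
25.5	36.0283	34.4046	0.127633	1.49608	31.7862
26	34.2988	32.7107	0.127863	1.46017	30.2696
26.5	32.6845	31.1302	0.128069	1.42624	28.8514
27	31.1758	29.6535	0.128252	1.39411	27.5234
27.5	29.764	28.272	0.128416	1.36363	26.2786
28	28.4413	26.978	0.128562	1.33467	25.1104
28.5	27.2005	25.7647	0.12869	1.30711	24.0128
29	26.0352	24.6256	0.128803	1.28084	22.9805
29.5	24.9397	23.555	0.128901	1.25577	22.0087
30	23.9087	22.5479	0.128986	1.23182	21.0928
30.5	22.9374	21.5994	0.129058	1.20891	20.2288
31	22.0214	20.7053	0.129119	1.18698	19.4131
31.5	21.1567	19.8616	0.129169	1.16597	18.6422
32	20.3398	19.0648	0.129208	1.14582	17.9131
32.5	19.5672	18.3115	0.129238	1.12648	17.2229
33	18.836	17.5989	0.129259	1.10791	16.5689
33.5	18.1434	16.9241	0.129271	1.09005	15.9489
34	17.4867	16.2846	0.129276	1.07289	15.3605
34.5	16.8637	15.678	0.129273	1.05637	14.8018
35	16.2721	15.1023	0.129263	1.04046	14.2708
35.5	15.7099	14.5555	0.129246	1.02514	13.7658
36	15.1753	14.0357	0.129223	1.01037	13.2853
36.5	14.6666	13.5413	0.129194	0.996128	12.8277
37	14.1822	13.0706	0.129159	0.982388	12.3916
37.5	13.7206	12.6223	0.129119	0.969127	11.9758
38	13.2805	12.1951	0.129074	0.956321	11.5791
38.5	12.8605	11.7875	0.129024	0.943951	11.2004
39	12.4596	11.3986	0.12897	0.931996	10.8386
39.5	12.0766	11.0273	0.128911	0.920439	10.4928
40	11.7106	10.6725	0.128848	0.909261	10.1622
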