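# energy_keV	mu_total	mu_pe	mu_incoh	mu_coh	mu_en
1	84206.3	84198.8	0.00865075	7.49212	84197.9
1.2	49630	49622.7	0.0119178	7.34375	49622.7
1.4	31741.9	31734.7	0.0154588	7.18265	31734.7
1.6	21552.6	21545.6	0.0191867	7.01276	21545.6
1.8	15318.3	15311.4	0.0230307	6.83726	15311.4
2	11286.9	11280.3	0.0269354	6.65867	11280.3
2.2	8562.69	8556.18	0.0308579	6.47894	8556.18
2.4	6654.37	6648.03	0.0347652	6.29956	6648.03
2.6	5277.04	5270.88	0.0386313	6.12173	5270.88
2.8	4257.54	4251.55	0.0424354	5.94642	4251.55
3	3486.42	3480.6	0.0461607	5.7744	3480.6
3.2	2892.15	2886.5	0.0497938	5.6063	2886.5
3.4	2426.62	2421.12	0.053324	5.44262	2421.12
3.6	2056.64	2051.3	0.0567434	5.28374	2051.3
3.8	1758.8	1753.61	0.0600465	5.12994	1753.61
4	1516.28	1511.23	0.0632298	4.98138	1511.24
4.2	1316.75	1311.85	0.0662919	4.83816	1311.85
4.4	1151.06	1146.29	0.0692326	4.7003	1146.29
4.6	1012.29	1007.65	0.072053	4.56776	1007.65
4.8	895.164	890.648	0.0747553	4.44046	890.649
5	795.608	791.212	0.0773422	4.31829	791.213
5.2	710.43	706.149	0.079817	4.20111	706.15
5.4	637.113	632.942	0.0821835	4.08877	632.943
5.6	573.653	569.588	0.0844456	3.98109	569.589
5.8	518.44	514.475	0.0866074	3.8779	514.476
6	470.17	466.302	0.088673	3.77902	466.303
6.2	427.779	424.004	0.0906466	3.68426	424.005
6.4	390.395	386.709	0.0925326	3.59343	386.71
6.6	357.295	353.695	0.0943351	3.50636	353.696
6.8	327.881	324.362	0.0960581	3.42286	324.363
7	301.65	298.21	0.0977058	3.34276	298.211
7.2	278.181	274.816	0.0992821	3.26587	274.817
7.4	257.118	253.825	0.100791	3.19202	253.826
7.6	238.158	234.934	0.102236	3.12106	234.936
7.8	221.044	217.887	0.10362	3.05282	217.889
8	205.555	202.463	0.104948	2.98715	202.464
8.2	191.502	188.472	0.106221	2.9239	188.473
8.4	178.721	175.75	0.107445	2.86293	175.752
8.6	167.07	164.157	0.10862	2.80411	164.159
8.8	156.427	153.57	0.109751	2.74733	153.572
9	146.684	143.881	0.110839	2.69245	143.883
9.2	137.747	134.996	0.111887	2.63936	134.998
9.4	129.535	126.834	0.112898	2.58798	126.836
9.6	121.974	119.322	0.113873	2.53819	119.324
9.8	115.001	112.396	0.114815	2.48992	112.398
10	108.559	106	0.115725	2.44307	106.002
10.5	94.4642	92.0146	0.117873	2.3317	92.017
11	82.7496	80.402	0.119855	2.22774	80.4045
11.5	72.9297	70.6777	0.121692	2.13034	70.6803
12	64.6335	62.4713	0.123399	2.0388	62.474
12.5	57.5742	55.4967	0.124988	1.95256	55.4996
13	51.5278	49.5302	0.126469	1.87116	49.5333
13.5	46.3175	44.3954	0.127851	1.79422	44.3986
14	41.8022	39.9516	0.129143	1.72142	39.955
14.5	37.8688	36.086	0.130349	1.65248	36.0895
15	34.4257	32.707	0.131475	1.58716	32.7107
15.5	31.398	29.7402	0.132527	1.52525	29.744
16	28.7243	27.1243	0.133508	1.46655	27.1282
16.5	26.3539	24.8086	0.134424	1.41089	24.8127
17	24.2446	22.7512	0.135277	1.3581	22.7554
17.5	22.3609	20.9168	0.136072	1.30803	20.9211
18	20.6733	19.2759	0.136812	1.26054	19.2804
18.5	19.1566	17.8036	0.137499	1.21548	17.8082
19	17.7895	16.4786	0.138137	1.17272	16.4834
19.5	16.5538	15.2829	0.138729	1.13214	15.2878
20	15.4339	14.201	0.139278	1.09362	14.206
20.5	14.4165	13.2196	0.139785	1.05705	13.2248
21	13.4899	12.3274	0.140254	1.02232	12.3326
21.5	12.6442	11.5142	0.140686	0.989326	11.5196
22	11.8707	10.7716	0.141084	0.95797	10.7771
22.5	11.1616	10.092	0.14145	0.928161	10.0977
23	10.5104	9.4688	0.141786	0.899811	9.47461
23.2198	10.2409	9.2112	0.141925	0.887789	9.21707
23.22	57.029	55.9993	0.141925	0.887778	23.2555
23.5	55.1335	54.1186	0.142094	0.872838	22.8519
24	51.9564	50.9669	0.142374	0.847163	22.1351
24.5	49.0235	48.0581	0.14263	0.822713	21.4272
25	46.3115	45.3692	0.142862	0.799445	20.7317
25.5	43.8002	42.8796	0.143067	0.777509	20.0513
26	41.4711	40.571	0.143247	0.756831	19.3877
26.5	39.3079	38.4272	0.143404	0.73729	18.7424
27	37.296	36.4337	0.143541	0.718784	18.1163
27.5	35.4222	34.5774	0.143659	0.701224	17.5099
28	33.6748	32.8465	0.14376	0.684533	16.9235
28.5	32.0432	31.2307	0.143845	0.668642	16.3572
29	30.5179	29.7205	0.143915	0.653493	15.8108
29.5	29.0902	28.3072	0.143972	0.639032	15.2841
30	27.7525	26.9833	0.144017	0.625211	14.7767
30.5	26.4976	25.7416	0.14405	0.611988	14.2882
31	25.3193	24.5759	0.144072	0.599325	13.8181
31.5	24.2116	23.4804	0.144084	0.587187	13.3659
32	23.1694	22.4498	0.144086	0.575543	12.9309
32.5	22.1879	21.4794	0.14408	0.564364	12.5127
33	21.2625	20.5648	0.144065	0.553624	12.1105
33.5	20.3894	19.7021	0.144043	0.543298	11.7239
34	19.5649	18.8875	0.144013	0.533364	11.3522
34.5	18.7856	18.1178	0.143976	0.523802	10.9949
35	18.0484	17.3899	0.143933	0.514592	10.6514
35.5	17.3505	16.7009	0.143884	0.505717	10.3211
36	16.6892	16.0483	0.143829	0.497161	10.0035
36.5	16.0623	15.4296	0.143768	0.488908	9.69803
37	15.4674	14.8428	0.143702	0.480943	9.40423
37.5	14.9026	14.2857	0.143631	0.473253	9.12161
38	14.3658	13.7565	0.143556	0.465825	8.84968
38.5	13.8555	13.2534	0.143476	0.458649	8.58799
39	13.37	12.7749	0.143392	0.451711	8.33611
39.5	12.9077	12.3194	0.143305	0.445002	8.09361
40	12.4673	11.8855	0.143213	0.438512	7.86011
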