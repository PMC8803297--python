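# energy_keV	mu_total	mu_pe	mu_incoh	mu_coh	mu_en
1	2793.87	2792.7	0.0186012	1.155	2793.57
1.2	1696.68	1695.54	0.0256316	1.11309	1696.48
1.4	1109.14	1108.04	0.0332043	1.06762	1109
1.6	763.688	762.627	0.0410821	1.01994	763.581
1.8	547	545.979	0.049058	0.971256	546.914
2	404.479	403.499	0.0569615	0.922574	404.407
2.2	307.072	306.133	0.0646606	0.874707	307.01
2.4	238.344	237.444	0.0720594	0.828267	238.289
2.6	188.529	187.666	0.0790937	0.783688	188.478
2.8	151.579	150.752	0.0857255	0.741254	151.532
3	123.618	122.825	0.0919373	0.701128	123.529
3.2	102.085	101.324	0.0977271	0.663378	101.95
3.4	85.2447	84.5135	0.103103	0.628004	85.0762
3.6	71.8911	71.188	0.108082	0.594953	71.6774
3.8	61.1715	60.4947	0.112684	0.56414	60.9108
4	52.4709	51.8185	0.116931	0.535457	52.1751
4.2	45.337	44.7073	0.120849	0.508784	45.0152
4.4	39.43	38.8215	0.124462	0.483995	39.089
4.6	34.4949	33.9061	0.127792	0.46096	34.14
4.8	30.3385	29.7681	0.130864	0.439554	29.9736
5	26.8124	26.259	0.133698	0.419655	26.4405
5.2	23.802	23.2645	0.136315	0.401146	23.4255
5.4	21.2199	20.6973	0.138734	0.383917	20.8408
5.6	18.996	18.4872	0.14097	0.367866	18.6156
5.8	17.0728	16.5769	0.143041	0.352897	16.6922
6	15.4031	14.9192	0.14496	0.33892	15.0232
6.2	13.9475	13.4749	0.146742	0.325856	13.5691
6.4	12.6726	12.2106	0.148396	0.313628	12.2962
6.6	11.5507	11.0986	0.149935	0.302169	11.1767
6.8	10.5593	10.1165	0.151368	0.291416	10.1879
7	9.67953	9.24551	0.152705	0.281312	9.31101
7.2	8.896	8.47025	0.153952	0.271804	8.5305
7.4	8.19572	7.77776	0.155118	0.262846	7.83334
7.6	7.56779	7.15719	0.156209	0.254395	7.20858
7.8	7.003	6.59936	0.15723	0.246411	6.64699
8	6.49354	6.09649	0.158188	0.238858	6.14075
8.2	6.03276	5.64197	0.159087	0.231704	5.68157
8.4	5.61508	5.23022	0.159932	0.22492	5.26573
8.6	5.23566	4.85645	0.160726	0.218478	4.88836
8.8	4.89031	4.51648	0.161474	0.212354	4.54521
9	4.57536	4.20666	0.162179	0.206525	4.23258
9.2	4.2876	3.92378	0.162843	0.200971	3.94722
9.4	4.0242	3.66506	0.163471	0.195672	3.6863
9.6	3.78269	3.42801	0.164063	0.190613	3.4473
9.8	3.56087	3.21048	0.164623	0.185775	3.22804
10	3.35682	3.01052	0.165152	0.181146	3.02654
10.5	2.91359	2.57684	0.166356	0.1704	2.59154
11	2.54911	2.22101	0.167409	0.160694	2.23461
11.5	2.2468	1.92659	0.168333	0.15188	1.93927
12	1.99406	1.68108	0.169146	0.143836	1.69299
12.5	1.78121	1.47488	0.169862	0.136463	1.48614
13	1.60071	1.30054	0.170493	0.129676	1.31125
13.5	1.44668	1.15223	0.171051	0.123407	1.16248
14	1.31446	1.02532	0.171542	0.117597	1.03519
14.5	1.20031	0.916142	0.171975	0.112195	0.92569
15	1.10126	0.821746	0.172356	0.107161	0.831029
15.5	1.01489	0.739738	0.17269	0.102458	0.748533
16	0.939188	0.668152	0.172982	0.0980545	0.676558
16.5	0.872542	0.605382	0.173236	0.0939242	0.613481
17	0.81361	0.550112	0.173454	0.0900436	0.557972
17.5	0.761287	0.501254	0.173641	0.0863921	0.50893
18	0.714655	0.457905	0.173798	0.0829514	0.465445
18.5	0.672946	0.419312	0.173929	0.0797054	0.426754
19	0.635516	0.384841	0.174035	0.0766397	0.392219
19.5	0.601818	0.353959	0.174118	0.0737413	0.361299
20	0.57139	0.326211	0.174181	0.0709985	0.333537
20.5	0.544114	0.301213	0.174501	0.0684007	0.3086
21	0.519375	0.278641	0.174796	0.0659383	0.286098
21.5	0.496887	0.258215	0.175069	0.0636024	0.265751
22	0.4764	0.239695	0.175321	0.061385	0.247316
22.5	0.457697	0.222867	0.175552	0.0592784	0.23058
23	0.440589	0.207549	0.175764	0.0572759	0.215358
23.5	0.424907	0.193579	0.175958	0.0553712	0.201489
24	0.410508	0.180814	0.176135	0.0535582	0.188831
24.5	0.397261	0.169132	0.176297	0.0518315	0.177257
25	0.385054	0.158423	0.176443	0.0501884	0.166659
25.5	0.373803	0.148589	0.176573	0.0486421	0.156939
26	0.363419	0.139544	0.176687	0.0471877	0.14801
26.5	0.353817	0.131213	0.176787	0.0458165	0.139797
27	0.344923	0.123529	0.176873	0.0445209	0.132231
27.5	0.336672	0.11643	0.176948	0.0432943	0.125253
28	0.329006	0.109864	0.177011	0.042131	0.118808
28.5	0.321871	0.103782	0.177063	0.0410259	0.112848
29	0.315222	0.0981411	0.177106	0.0399747	0.107329
29.5	0.309016	0.092903	0.177139	0.0389733	0.102214
30	0.303215	0.0880329	0.177164	0.0380183	0.0974677
30.5	0.297663	0.0834995	0.177057	0.0371063	0.093051
31	0.292454	0.0792741	0.176945	0.0362346	0.0889425
31.5	0.287559	0.0753306	0.176827	0.0354007	0.0851159
32	0.282953	0.0716458	0.176705	0.034602	0.081548
32.5	0.278614	0.0681985	0.176579	0.0338366	0.0782174
33	0.27452	0.0649698	0.176448	0.0331024	0.0751053
33.5	0.270653	0.0619424	0.176313	0.0323976	0.0721942
34	0.266996	0.0591006	0.176175	0.0317207	0.0694686
34.5	0.263534	0.0564305	0.176033	0.03107	0.0669141
35	0.260252	0.053919	0.175889	0.0304442	0.064518
35.5	0.257137	0.0515544	0.175741	0.0298419	0.0622684
36	0.254178	0.0493261	0.17559	0.0292621	0.0601547
36.5	0.251365	0.0472242	0.175437	0.0287034	0.0581669
37	0.248686	0.0452399	0.175282	0.0281649	0.0562962
37.5	0.246134	0.0433649	0.175124	0.0276456	0.0545343
38	0.2437	0.0415918	0.174964	0.0271446	0.0528738
38.5	0.241376	0.0399136	0.174801	0.026661	0.0513077
39	0.239155	0.038324	0.174637	0.026194	0.0498296
39.5	0.237032	0.0368172	0.174472	0.0257428	0.0484338
40	0.234999	0.0353878	0.174304	0.0253067	0.0471147
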