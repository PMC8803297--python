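# energy_keV	mu_total	mu_pe	mu_incoh	mu_coh	mu_en
1	2787.9	2785.98	0.0145521	1.90115	2786.43
1.2	1717.97	1716.11	0.0197927	1.83676	1716.65
1.4	1136.12	1134.33	0.025325	1.76933	1134.9
1.5595	846.638	844.888	0.0298245	1.71442	845.474
1.5597	2749.01	2747.26	0.0298302	1.71435	2681.46
1.6	2591.6	2589.87	0.0309807	1.701	2529.23
1.8	1967.61	1965.94	0.0366307	1.63335	1924.55
2	1524.82	1523.21	0.0421828	1.56744	1494.16
2.2	1197.42	1195.87	0.0475751	1.50392	1175.12
2.4	952.591	951.095	0.0527697	1.44313	936.018
2.6	768.021	766.578	0.0577453	1.38522	755.435
2.8	627.467	626.075	0.0624923	1.33019	617.704
3	519.249	517.904	0.0670084	1.27795	511.518
3.2	434.898	433.598	0.0712963	1.22841	428.656
3.4	368.096	366.839	0.0753618	1.18142	362.969
3.6	314.397	313.181	0.0792126	1.13685	310.09
3.8	270.666	269.488	0.0828576	1.09456	266.976
4	234.645	233.505	0.0863068	1.0544	231.444
4.2	204.683	203.577	0.0895702	1.01625	201.872
4.4	179.561	178.488	0.0926582	0.979971	177.066
4.6	158.348	157.307	0.0955809	0.945448	156.113
4.8	140.32	139.309	0.0983483	0.912564	138.3
5	124.906	123.924	0.10097	0.881216	123.065
5.2	111.653	110.698	0.103455	0.851303	109.964
5.4	100.201	99.272	0.105811	0.822739	98.6401
5.6	90.2565	89.353	0.108047	0.79544	88.8068
5.8	81.5836	80.7041	0.11017	0.769333	80.2297
6	73.9871	73.1305	0.112187	0.744351	72.7169
6.2	67.3063	66.4717	0.114104	0.720431	66.1096
6.4	61.4067	60.5933	0.115926	0.697517	60.2752
6.6	56.1768	55.3836	0.117659	0.675559	55.1031
6.8	51.5236	50.7498	0.119309	0.654508	50.5018
7	47.3694	46.6142	0.120879	0.634321	46.3942
7.2	43.6488	42.9114	0.122374	0.614958	42.7158
7.4	40.3064	39.5862	0.123798	0.596381	39.4117
7.6	37.2953	36.5916	0.125155	0.578553	36.4356
7.8	34.5753	33.8874	0.126447	0.561443	33.7476
8	32.112	31.4393	0.127679	0.545019	31.3137
8.2	29.8759	29.2178	0.128854	0.52925	29.1041
8.4	27.8415	27.1974	0.129973	0.514109	27.0942
8.6	25.9868	25.3562	0.131041	0.499568	25.2624
8.8	24.2926	23.6749	0.132059	0.485602	23.5895
9	22.742	22.1368	0.133029	0.472186	22.0589
9.2	21.3204	20.7271	0.133955	0.459297	20.6559
9.4	20.0145	19.4328	0.134839	0.446911	19.3677
9.6	18.8131	18.2425	0.135681	0.435006	18.1828
9.8	17.706	17.146	0.136485	0.423563	17.0912
10	16.6842	16.1343	0.137253	0.41256	16.0841
10.5	14.4522	13.9264	0.139021	0.386857	13.8879
11	12.6025	12.0984	0.140596	0.363507	12.0691
11.5	11.0568	10.5726	0.142	0.342257	10.5504
12	9.75552	9.28938	0.143252	0.322878	9.27285
12.5	8.65231	8.20277	0.144369	0.305168	8.19069
13	7.71106	7.27675	0.145368	0.288945	7.26822
13.5	6.90325	6.48294	0.146262	0.274048	6.47727
14	6.20613	5.79874	0.147061	0.260337	5.79538
14.5	5.60147	5.20601	0.147776	0.247686	5.20454
15	5.07449	4.69008	0.148417	0.235986	4.69016
15.5	4.61316	4.23903	0.148991	0.22514	4.24031
16	4.20762	3.84305	0.149504	0.215064	3.84534
16.5	3.84974	3.4941	0.149964	0.205683	3.49723
17	3.53276	3.18545	0.150374	0.196932	3.18929
17.5	3.25102	2.91153	0.15074	0.188753	2.91597
18	2.99978	2.66762	0.151065	0.181096	2.67257
18.5	2.77505	2.44978	0.151354	0.173914	2.45517
19	2.57343	2.25465	0.151609	0.167167	2.26042
19.5	2.39203	2.07938	0.151834	0.160821	2.08548
20	2.2284	1.92152	0.15203	0.154843	1.92792
20.5	2.08049	1.779	0.15228	0.149205	1.78546
21	1.9464	1.65001	0.152503	0.143881	1.65654
21.5	1.82454	1.53299	0.152703	0.138849	1.53959
22	1.71357	1.4266	0.152881	0.134086	1.43328
22.5	1.61227	1.32966	0.153038	0.129575	1.33642
23	1.51963	1.24116	0.153176	0.125298	1.248
23.5	1.43474	1.1602	0.153296	0.121239	1.16713
24	1.35679	1.08601	0.153399	0.117385	1.09302
24.5	1.2851	1.01789	0.153487	0.113722	1.025
25	1.21905	0.955254	0.15356	0.11024	0.96245
25.5	1.15812	0.897554	0.153617	0.106951	0.904842
26	1.10182	0.84432	0.15366	0.103845	0.851703
26.5	1.04973	0.795132	0.153689	0.100906	0.80261
27	1.00144	0.749617	0.153705	0.09812	0.757192
27.5	0.956628	0.707441	0.153711	0.0954762	0.715114
28	0.914976	0.668307	0.153705	0.0929638	0.676078
28.5	0.876211	0.631948	0.15369	0.0905734	0.639818
29	0.840086	0.598124	0.153666	0.0882966	0.606094
29.5	0.80638	0.566621	0.153633	0.0861255	0.574692
30	0.774891	0.537245	0.153593	0.0840535	0.545416
30.5	0.745394	0.509821	0.153499	0.082074	0.518095
31	0.717773	0.484193	0.153399	0.0801815	0.492569
31.5	0.691882	0.460219	0.153293	0.0783706	0.468696
32	0.667588	0.437769	0.153182	0.0766364	0.446348
32.5	0.644768	0.416727	0.153066	0.0749747	0.425407
33	0.623313	0.396986	0.152946	0.0733811	0.405766
33.5	0.603122	0.378448	0.152822	0.0718521	0.387329
34	0.584103	0.361025	0.152693	0.0703839	0.370006
34.5	0.566171	0.344636	0.152561	0.0689735	0.353716
35	0.549249	0.329206	0.152426	0.0676177	0.338385
35.5	0.533268	0.314667	0.152288	0.0663137	0.323945
36	0.518162	0.300957	0.152146	0.0650588	0.310333
36.5	0.503871	0.288019	0.152002	0.0638507	0.297493
37	0.490341	0.275799	0.151855	0.062687	0.285371
37.5	0.477521	0.26425	0.151705	0.0615655	0.273919
38	0.465365	0.253327	0.151554	0.0604843	0.263092
38.5	0.45383	0.242989	0.1514	0.0594413	0.25285
39	0.442876	0.233197	0.151244	0.0584349	0.243153
39.5	0.432467	0.223917	0.151087	0.0574633	0.233968
40	0.422568	0.215116	0.150927	0.056525	0.225261
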