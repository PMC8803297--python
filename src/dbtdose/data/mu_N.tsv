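# energy_keV	mu_total	mu_pe	mu_incoh	mu_coh	mu_en
1	3311	3309.7	0.0141724	1.29081	3310.67
1.2	2010.51	2009.24	0.0196219	1.24809	2010.3
1.4	1313.26	1312.04	0.0256095	1.20108	1313.13
1.6	902.916	901.733	0.0319701	1.15105	902.826
1.8	645.68	644.542	0.0385483	1.09922	645.615
2	476.9	475.808	0.0452046	1.04668	476.852
2.2	361.873	360.827	0.0518198	0.994368	361.837
2.4	280.842	279.84	0.0582968	0.943048	280.814
2.6	222.135	221.177	0.0645607	0.893319	222.113
2.8	178.58	177.663	0.0705572	0.845613	178.562
3	145.6	144.724	0.0762506	0.800221	145.585
3.2	120.185	119.347	0.0816207	0.757311	120.166
3.4	100.306	99.5023	0.0866595	0.716953	100.186
3.6	84.5488	83.7783	0.0913687	0.679143	84.3539
3.8	71.9092	71.1696	0.0957568	0.643819	71.6588
4	61.66	60.9493	0.0998371	0.610884	61.3684
4.2	53.2641	52.5802	0.103626	0.580216	52.9419
4.4	46.3131	45.6543	0.107141	0.551679	45.9686
4.6	40.5024	39.8668	0.1104	0.525133	40.1414
4.8	35.6028	34.989	0.113422	0.500438	35.2302
5	31.44	30.8463	0.116225	0.477457	31.0592
5.2	27.8809	27.306	0.118824	0.456061	27.4946
5.4	24.8276	24.2702	0.121237	0.436127	24.438
5.6	22.2005	21.6595	0.123478	0.417543	21.8095
5.8	19.9331	19.4074	0.12556	0.400201	19.542
6	17.97	17.4585	0.127495	0.384006	17.5798
6.2	16.264	15.7658	0.129296	0.368866	15.8756
6.4	14.7734	14.2877	0.130973	0.354701	14.3874
6.6	13.4639	12.9899	0.132536	0.341432	13.0808
6.8	12.3077	11.8448	0.133993	0.328992	11.9278
7	11.2823	10.8296	0.135353	0.317316	10.9058
7.2	10.3689	9.92593	0.136624	0.306344	9.99594
7.4	9.55214	9.11831	0.137812	0.296023	9.18284
7.6	8.81916	8.39393	0.138923	0.286303	8.45356
7.8	8.15915	7.74204	0.139964	0.277138	7.79726
8	7.563	7.15357	0.14094	0.268486	7.20482
8.2	7.02306	6.62089	0.141855	0.260308	6.66666
8.4	6.53303	6.13774	0.142715	0.252569	6.17869
8.6	6.0875	5.69874	0.143524	0.245237	5.73544
8.8	5.68171	5.29915	0.144285	0.23828	5.3321
9	5.31149	4.93482	0.145001	0.231673	4.96445
9.2	4.97315	4.60208	0.145676	0.225389	4.62878
9.4	4.66344	4.29772	0.146314	0.219406	4.32182
9.6	4.3795	4.01888	0.146915	0.213702	4.04067
9.8	4.11877	3.76303	0.147484	0.208258	3.78277
10	3.879	3.52792	0.148022	0.203057	3.54584
10.5	3.35857	3.01831	0.149247	0.191008	3.03463
11	2.93099	2.60051	0.150319	0.180156	2.6155
11.5	2.57661	2.25502	0.151263	0.170321	2.26888
12	2.28052	1.96707	0.152096	0.161359	1.97997
12.5	2.03129	1.7253	0.152833	0.153154	1.7374
13	1.82005	1.52095	0.153486	0.145609	1.53236
13.5	1.63985	1.34714	0.154067	0.138643	1.35797
14	1.48521	1.19844	0.154583	0.132189	1.20878
14.5	1.35176	1.07053	0.155041	0.126192	1.08045
15	1.236	0.959948	0.155448	0.120604	0.96952
15.5	1.13508	0.863886	0.155809	0.115383	0.872845
16	1.04666	0.78004	0.156128	0.110496	0.788505
16.5	0.968851	0.706531	0.15641	0.10591	0.714597
17	0.900073	0.641814	0.156658	0.101601	0.649561
17.5	0.839035	0.584617	0.156874	0.0975441	0.59211
18	0.784661	0.53388	0.157062	0.0937193	0.541174
18.5	0.73605	0.488719	0.157223	0.0901083	0.495861
19	0.692447	0.448391	0.157361	0.086695	0.45542
19.5	0.653211	0.412271	0.157476	0.0834647	0.419219
20	0.6178	0.379825	0.157571	0.0804044	0.38672
20.5	0.586053	0.350603	0.157948	0.0775022	0.35753
21	0.55727	0.324223	0.1583	0.0747475	0.331195
21.5	0.531117	0.300358	0.158629	0.0721303	0.307384
22	0.5073	0.278722	0.158936	0.0696418	0.285811
22.5	0.485566	0.259069	0.159223	0.0672737	0.266228
23	0.465691	0.241181	0.159491	0.0650185	0.248417
23.5	0.44748	0.22487	0.159741	0.0628693	0.232188
24	0.430763	0.20997	0.159973	0.0608195	0.217376
24.5	0.415389	0.196336	0.16019	0.0588633	0.203832
25	0.401226	0.183838	0.16039	0.0569982	0.19143
25.5	0.388181	0.172363	0.160573	0.0552446	0.180053
26	0.376149	0.161812	0.16074	0.0535974	0.169602
26.5	0.365031	0.152094	0.160891	0.0520462	0.159988
27	0.354741	0.143132	0.161027	0.0505821	0.15113
27.5	0.345201	0.134853	0.161151	0.0491973	0.142958
28	0.336344	0.127197	0.161262	0.047885	0.135409
28.5	0.328107	0.120106	0.161362	0.0466393	0.128427
29	0.320436	0.11353	0.161451	0.0454549	0.121961
29.5	0.313281	0.107424	0.161531	0.0443273	0.115966
30	0.3066	0.101747	0.161601	0.0432523	0.110401
30.5	0.300217	0.0964635	0.161528	0.0422262	0.105221
31	0.294234	0.0915392	0.161449	0.0412457	0.100402
31.5	0.288617	0.086944	0.161365	0.0403079	0.0959116
32	0.283336	0.0826507	0.161275	0.0394101	0.0917236
32.5	0.278366	0.0786348	0.161181	0.0385497	0.087813
33	0.273681	0.074874	0.161083	0.0377245	0.0841576
33.5	0.269261	0.0713484	0.16098	0.0369326	0.0807372
34	0.265085	0.0680396	0.160874	0.036172	0.0775336
34.5	0.261135	0.0649312	0.160763	0.0354409	0.0745303
35	0.257396	0.0620081	0.16065	0.0347378	0.071712
35.5	0.253851	0.0592567	0.160533	0.0340612	0.0690652
36	0.250487	0.0566645	0.160413	0.0334097	0.0665773
36.5	0.247292	0.0542201	0.16029	0.0327821	0.0642369
37	0.244255	0.051913	0.160165	0.0321771	0.0620334
37.5	0.241364	0.0497337	0.160037	0.0315937	0.0599574
38	0.23861	0.0476734	0.159906	0.0310308	0.058
38.5	0.235985	0.0457241	0.159774	0.0304874	0.0561531
39	0.23348	0.0438784	0.159639	0.0299627	0.0544094
39.5	0.231087	0.0421294	0.159502	0.0294557	0.052762
40	0.2288	0.0404709	0.159363	0.0289657	0.0512046
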