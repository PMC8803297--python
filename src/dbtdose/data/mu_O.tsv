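# energy_keV	mu_total	mu_pe	mu_incoh	mu_coh	mu_en
1	4590	4588.49	0.0113272	1.50149	4589.54
1.2	2828.01	2826.53	0.0158449	1.46103	2827.73
1.4	1869.06	1867.63	0.0208696	1.41594	1868.88
1.6	1297.15	1295.76	0.0262817	1.3673	1297.02
1.8	934.717	933.369	0.0319654	1.31613	934.623
2	694.9	693.599	0.0378129	1.26338	694.831
2.2	530.334	529.08	0.0437274	1.20994	530.281
2.4	413.688	412.482	0.0496255	1.15655	413.647
2.6	328.701	327.542	0.0554379	1.10383	328.668
2.8	265.32	264.207	0.0611088	1.05229	265.294
3	217.1	216.031	0.0665957	1.00233	217.078
3.2	179.779	178.752	0.0718674	0.954227	179.761
3.4	150.472	149.486	0.076903	0.908178	150.456
3.6	127.161	126.215	0.0816899	0.864305	127.082
3.8	108.403	107.494	0.0862225	0.822667	108.233
4	93.15	92.2762	0.0905003	0.783274	92.9103
4.2	80.6224	79.7817	0.0945272	0.746099	80.3301
4.4	70.2268	69.4174	0.09831	0.711085	69.8946
4.6	61.5183	60.7382	0.101858	0.678156	61.156
4.8	54.1615	53.4091	0.105181	0.647224	53.7767
5	47.9	47.1735	0.108291	0.618189	47.4983
5.2	42.5377	41.8355	0.1112	0.590948	42.1238
5.4	37.9292	37.2498	0.113919	0.565396	37.5067
5.6	33.9564	33.2985	0.116461	0.541429	33.5283
5.8	30.5208	29.883	0.118837	0.518944	30.0894
6	27.54	26.9211	0.121059	0.497843	27.1073
6.2	24.9444	24.3432	0.123137	0.478032	24.5118
6.4	22.6724	22.0879	0.125081	0.459421	22.241
6.6	20.6733	20.1044	0.1269	0.441925	20.244
6.8	18.9059	18.3518	0.128604	0.425465	18.4794
7	17.3364	16.7962	0.130201	0.409968	16.9132
7.2	15.937	15.4099	0.131699	0.395364	15.5175
7.4	14.6845	14.1698	0.133104	0.381591	14.2689
7.6	13.5596	13.0566	0.134424	0.368588	13.1482
7.8	12.5461	12.0541	0.135663	0.356302	12.1388
8	11.63	11.1485	0.136829	0.344682	11.2271
8.2	10.7999	10.3283	0.137927	0.333681	10.3983
8.4	10.046	9.58381	0.13896	0.323258	9.64641
8.6	9.36022	8.90692	0.139933	0.313372	8.9629
8.8	8.73519	8.29035	0.140851	0.303987	8.34048
9	8.16453	7.72775	0.141718	0.29507	7.7727
9.2	7.64266	7.21353	0.142535	0.28659	7.25389
9.4	7.1646	6.74277	0.143308	0.278517	6.77905
9.6	6.72598	6.31112	0.144038	0.270827	6.34376
9.8	6.32293	5.91471	0.144729	0.263495	5.94412
10	5.952	5.55012	0.145382	0.256497	5.57666
10.5	5.14584	4.75864	0.146869	0.240335	4.78263
11	4.48228	4.10826	0.14817	0.225853	4.13008
11.5	3.93131	3.56919	0.149312	0.212812	3.58918
12	3.47017	3.11884	0.150317	0.201014	3.13726
12.5	3.08136	2.73986	0.151203	0.190292	2.75694
13	2.7513	2.41881	0.151986	0.180505	2.43473
13.5	2.46934	2.14513	0.152679	0.171536	2.16005
14	2.22707	1.91049	0.153293	0.163286	1.92456
14.5	2.01776	1.70825	0.153837	0.155669	1.72158
15	1.836	1.53307	0.15432	0.148615	1.54575
15.5	1.67741	1.3806	0.154747	0.142061	1.39222
16	1.53841	1.24732	0.155126	0.135956	1.25808
16.5	1.41605	1.13034	0.155461	0.130253	1.14037
17	1.30792	1.02725	0.155757	0.124915	1.03669
17.5	1.21199	0.936069	0.156016	0.119906	0.945022
18	1.12659	0.85515	0.156243	0.115198	0.863704
18.5	1.0503	0.783099	0.156441	0.110764	0.791329
19	0.981941	0.718748	0.156611	0.106582	0.726715
19.5	0.920492	0.661104	0.156757	0.102631	0.668862
20	0.8651	0.609326	0.15688	0.0988936	0.616919
20.5	0.81533	0.562695	0.157282	0.0953535	0.570254
21	0.770246	0.520591	0.157658	0.0919965	0.528135
21.5	0.729305	0.482486	0.158009	0.0888097	0.490031
22	0.692039	0.44792	0.158338	0.0857815	0.455481
22.5	0.658041	0.416496	0.158644	0.0829012	0.424085
23	0.626959	0.387869	0.158931	0.0801595	0.395496
23.5	0.598483	0.361738	0.159198	0.0775475	0.369413
24	0.572345	0.33784	0.159447	0.0750573	0.345572
24.5	0.548306	0.315945	0.15968	0.0726816	0.32374
25	0.526162	0.295849	0.159896	0.0704173	0.303714
25.5	0.505754	0.277373	0.160093	0.0682876	0.285314
26	0.48692	0.260361	0.160273	0.0662865	0.268381
26.5	0.46951	0.244671	0.160437	0.0644017	0.252775
27	0.453388	0.23018	0.160585	0.0626228	0.238371
27.5	0.438436	0.216776	0.16072	0.0609404	0.225057
28	0.42455	0.204361	0.160842	0.0593464	0.212736
28.5	0.411633	0.192846	0.160953	0.0578338	0.201317
29	0.399602	0.182154	0.161052	0.0563963	0.190722
29.5	0.38838	0.172212	0.16114	0.0550282	0.18088
30	0.3779	0.162956	0.161219	0.0537246	0.171726
30.5	0.367967	0.154331	0.161155	0.0524809	0.163195
31	0.358661	0.146284	0.161084	0.0512932	0.155243
31.5	0.349934	0.138769	0.161007	0.0501578	0.147825
32	0.34174	0.131743	0.160926	0.0490715	0.140897
32.5	0.334039	0.12517	0.160838	0.048031	0.134422
33	0.326793	0.119013	0.160747	0.0470338	0.128364
33.5	0.319969	0.113241	0.16065	0.0460773	0.122692
34	0.313535	0.107826	0.16055	0.0451592	0.117376
34.5	0.307463	0.10274	0.160445	0.0442772	0.112391
35	0.301727	0.0979606	0.160337	0.0434296	0.107711
35.5	0.296304	0.0934646	0.160225	0.0426143	0.103315
36	0.291172	0.0892321	0.16011	0.0418298	0.0991832
36.5	0.286311	0.0852444	0.159992	0.0410744	0.0952958
37	0.281703	0.0814847	0.159871	0.0403467	0.0916363
37.5	0.27733	0.0779372	0.159748	0.0396453	0.0881888
38	0.273178	0.0745874	0.159621	0.0389689	0.0849389
38.5	0.269231	0.0714222	0.159493	0.0383164	0.0818734
39	0.265477	0.0684293	0.159362	0.0376865	0.07898
39.5	0.261904	0.0655974	0.159228	0.0370783	0.0762472
40	0.2585	0.062916	0.159093	0.0364907	0.0736647
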