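# energy_keV	mu_total	mu_pe	mu_incoh	mu_coh	mu_en
1	1185	1182.73	0.0174204	2.25664	1182.64
1.2	730.628	728.433	0.0233042	2.17095	728.379
1.4	484.194	482.081	0.029288	2.08366	482.046
1.5595	362.1	360.051	0.033988	2.01497	360.024
1.5597	3957	3954.95	0.0339938	2.01489	3829.48
1.6	3742.96	3740.93	0.0351603	1.99782	3625.22
1.8	2886.33	2884.38	0.0407803	1.91551	2805.06
2	2263	2261.12	0.0460696	1.83788	2205.14
2.2	1790.77	1788.96	0.0509976	1.7654	1748.68
2.4	1431.93	1430.17	0.0555664	1.69804	1400.65
2.6	1158.78	1157.08	0.0597978	1.63551	1135.03
2.8	949.583	947.942	0.0637228	1.57736	931.159
3	788	786.41	0.0673755	1.52311	773.411
3.2	661.817	660.274	0.0707883	1.47228	650.039
3.4	561.665	560.166	0.0739909	1.42446	551.992
3.6	480.936	479.48	0.077009	1.37927	472.87
3.8	414.992	413.576	0.0798647	1.33639	408.173
4	360.5	359.122	0.0825768	1.29556	354.664
4.2	315.03	313.688	0.0851611	1.25654	309.978
4.4	276.809	275.502	0.0876311	1.21914	272.392
4.6	244.475	243.202	0.0899979	1.18319	240.574
4.8	216.955	215.714	0.0922709	1.14857	213.481
5	193.4	192.19	0.0944581	1.11517	190.279
5.2	173.129	171.949	0.0965659	1.08288	170.305
5.4	155.589	154.438	0.0985996	1.05164	153.016
5.6	140.333	139.211	0.100564	1.02137	137.975
5.8	127.002	125.908	0.102461	0.992045	124.828
6	115.3	114.232	0.104295	0.96361	113.285
6.2	104.986	103.943	0.106069	0.936035	103.109
6.4	95.8595	94.8424	0.107783	0.909295	94.1051
6.6	87.7559	86.7631	0.10944	0.883368	86.109
6.8	80.5359	79.5666	0.111041	0.858233	78.9845
7	74.0827	73.1362	0.112587	0.833875	72.6165
7.2	68.2974	67.373	0.11408	0.810279	66.9076
7.4	63.0961	62.1932	0.115521	0.787428	61.7753
7.6	58.4073	57.5251	0.116911	0.76531	57.1488
7.8	54.1695	53.3073	0.11825	0.743909	52.9677
8	50.33	49.4872	0.119541	0.723211	49.18
8.2	46.8433	46.0193	0.120784	0.703202	45.7421
8.4	43.6699	42.864	0.12198	0.683864	42.6134
8.6	40.7755	39.9872	0.123131	0.665183	39.7602
8.8	38.1303	37.359	0.124238	0.647142	37.153
9	35.7082	34.9532	0.125301	0.629725	34.766
9.2	33.4862	32.7469	0.126324	0.612913	32.5766
9.4	31.4441	30.7201	0.127305	0.59669	30.5648
9.6	29.5642	28.8549	0.128248	0.581038	28.7132
9.8	27.8308	27.1357	0.129153	0.565938	27.0062
10	26.23	25.5486	0.130021	0.551373	25.43
10.5	22.7299	22.0807	0.132041	0.517183	21.9868
11	19.8251	19.2053	0.133859	0.485945	19.1306
11.5	17.3947	16.8018	0.135495	0.457393	16.7422
12	15.3461	14.7779	0.136967	0.431272	14.7302
12.5	13.6075	13.0618	0.138291	0.407347	13.0238
13	12.1226	11.5977	0.139482	0.385398	11.5674
13.5	10.847	10.3413	0.140554	0.365229	10.3173
14	9.74536	9.25718	0.141518	0.34666	9.23834
14.5	8.78904	8.31713	0.142386	0.329531	8.3025
15	7.955	7.49813	0.143167	0.313699	7.487
15.5	7.2244	6.78149	0.143871	0.299036	6.77358
16	6.58179	6.15186	0.144504	0.285428	6.14662
16.5	6.01442	5.59657	0.145074	0.272776	5.59357
17	5.51167	5.1051	0.145586	0.26099	5.10396
17.5	5.06466	4.66862	0.146047	0.249991	4.66905
18	4.66592	4.27975	0.14646	0.239709	4.2815
18.5	4.30914	3.93223	0.14683	0.230083	3.9351
19	3.98899	3.62078	0.14716	0.221056	3.6246
19.5	3.70091	3.34088	0.147455	0.212579	3.34551
20	3.441	3.08867	0.147717	0.204609	3.094
20.5	3.2058	2.86086	0.14783	0.197104	2.86635
21	2.99254	2.65459	0.147919	0.190031	2.66021
21.5	2.79872	2.46738	0.147984	0.183356	2.47314
22	2.62218	2.2971	0.148027	0.177051	2.30299
22.5	2.46103	2.14189	0.148051	0.171089	2.14791
23	2.31363	2.00013	0.148057	0.165447	2.00627
23.5	2.17855	1.8704	0.148045	0.160102	1.87666
24	2.05453	1.75148	0.148019	0.155034	1.75785
24.5	1.94046	1.64225	0.147978	0.150225	1.64874
25	1.83536	1.54177	0.147924	0.145661	1.54837
25.5	1.73838	1.44918	0.147857	0.141342	1.45589
26	1.64876	1.36373	0.147777	0.137252	1.37055
26.5	1.56581	1.28475	0.147687	0.133375	1.29167
27	1.48892	1.21164	0.147586	0.129693	1.21866
27.5	1.41754	1.14387	0.147476	0.126195	1.151
28	1.35119	1.08097	0.147357	0.122865	1.0882
28.5	1.28944	1.02251	0.14723	0.119694	1.02985
29	1.23188	0.968114	0.147097	0.116671	0.975553
29.5	1.17817	0.917433	0.146956	0.113785	0.924973
30	1.128	0.87016	0.14681	0.11103	0.8778
30.5	1.0811	0.826016	0.146689	0.108396	0.833765
31	1.03719	0.784751	0.146563	0.105877	0.792607
31.5	0.996033	0.746137	0.146431	0.103465	0.754099
32	0.957417	0.709968	0.146295	0.101154	0.718035
32.5	0.92115	0.676057	0.146153	0.09894	0.684227
33	0.887057	0.644233	0.146008	0.0968161	0.652505
33.5	0.854976	0.61434	0.145859	0.0947778	0.622714
34	0.824763	0.586236	0.145706	0.0928204	0.59471
34.5	0.796282	0.559793	0.145549	0.0909399	0.568366
35	0.769411	0.534889	0.14539	0.0891321	0.543561
35.5	0.744038	0.511418	0.145227	0.0873933	0.520187
36	0.72006	0.489278	0.145062	0.0857202	0.498143
36.5	0.697382	0.468379	0.144894	0.0841094	0.477339
37	0.675917	0.448635	0.144724	0.0825578	0.45769
37.5	0.655584	0.429969	0.144552	0.0810627	0.439119
38	0.636309	0.41231	0.144378	0.0796214	0.421553
38.5	0.618024	0.395591	0.144202	0.0782312	0.404926
39	0.600666	0.379752	0.144024	0.0768898	0.389179
39.5	0.584176	0.364736	0.143845	0.0755951	0.374254
40	0.5685	0.350492	0.143664	0.0743448	0.3601
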