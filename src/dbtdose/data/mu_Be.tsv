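# energy_keV	mu_total	mu_pe	mu_incoh	mu_coh	mu_en
1	604.1	603.482	0.0268245	0.591566	604.04
1.2	351.026	350.438	0.0355669	0.552402	350.991
1.4	221.247	220.689	0.0442292	0.513524	221.225
1.6	147.782	147.253	0.0524924	0.476364	147.767
1.8	103.194	102.693	0.0601627	0.441797	103.184
2	74.69	74.2126	0.0671471	0.41025	74.6825
2.2	55.6809	55.2257	0.0734242	0.381829	55.605
2.4	42.5455	42.1101	0.0790182	0.356435	42.3995
2.6	33.1939	32.7761	0.0839784	0.333853	33.0014
2.8	26.3655	25.9633	0.0883661	0.313816	26.142
3	21.27	20.8817	0.0922456	0.29604	21.0256
3.2	17.3954	17.0195	0.0956795	0.280248	17.1369
3.4	14.4004	14.0355	0.0987264	0.26618	14.1325
3.6	12.0515	11.6965	0.101439	0.253603	11.7775
3.8	10.1852	9.83904	0.103865	0.242305	9.90734
4	8.685	8.34685	0.106045	0.232103	8.40496
4.2	7.46626	7.13541	0.108014	0.222838	7.18526
4.4	6.46656	6.14238	0.109804	0.214373	6.18547
4.6	5.63926	5.32123	0.11144	0.206592	5.35874
4.8	4.94908	4.63673	0.112945	0.1994	4.66961
5	4.369	4.06195	0.114335	0.192714	4.09093
5.2	3.87812	3.57603	0.115626	0.186466	3.60173
5.4	3.46012	3.16269	0.116831	0.180601	3.18561
5.6	3.10212	2.80908	0.11796	0.175072	2.82963
5.8	2.79383	2.50496	0.119022	0.16984	2.52348
6	2.527	2.2421	0.120024	0.164872	2.25888
6.2	2.29496	2.01385	0.120973	0.160141	2.02911
6.4	2.09228	1.81478	0.121872	0.155623	1.82873
6.6	1.91449	1.64046	0.122728	0.151301	1.65327
6.8	1.75793	1.48723	0.123543	0.147156	1.49904
7	1.61953	1.35204	0.124321	0.143176	1.36298
7.2	1.49676	1.23235	0.125065	0.139346	1.24253
7.4	1.38749	1.12605	0.125776	0.135658	1.13556
7.6	1.28991	1.03135	0.126457	0.132101	1.04026
7.8	1.20251	0.946732	0.127111	0.128668	0.95512
8	1.124	0.870911	0.127738	0.125352	0.878835
8.2	1.05328	0.80279	0.128339	0.122145	0.810074
8.4	0.989387	0.741426	0.128918	0.119044	0.748155
8.6	0.93152	0.686006	0.129473	0.116042	0.692256
8.8	0.878974	0.635833	0.130007	0.113135	0.641667
9	0.831144	0.590305	0.13052	0.110319	0.59578
9.2	0.787506	0.548902	0.131014	0.107591	0.554065
9.4	0.747606	0.511171	0.131488	0.104946	0.516065
9.6	0.711045	0.476718	0.131945	0.102383	0.481379
9.8	0.677478	0.445198	0.132383	0.0998969	0.449658
10	0.6466	0.416308	0.132805	0.0974865	0.420596
10.5	0.579522	0.353959	0.13379	0.0917731	0.35817
11	0.524409	0.30325	0.134682	0.086478	0.307416
11.5	0.478779	0.261723	0.135487	0.0815687	0.265872
12	0.440714	0.227484	0.136214	0.0770161	0.231638
12.5	0.40873	0.199069	0.136868	0.0727931	0.203246
13	0.381666	0.175336	0.137455	0.0688745	0.179552
13.5	0.358611	0.155393	0.137981	0.0652368	0.15966
14	0.338845	0.138536	0.138451	0.0618581	0.142864
14.5	0.321794	0.124208	0.138869	0.058718	0.128606
15	0.307	0.111963	0.139239	0.0557975	0.116438
15.5	0.294085	0.10144	0.139566	0.0530787	0.10596
16	0.282724	0.0923254	0.139854	0.0505454	0.0969012
16.5	0.272655	0.0843676	0.140105	0.0481826	0.0890098
17	0.263669	0.0773705	0.140323	0.0459763	0.0820867
17.5	0.255602	0.071178	0.14051	0.0439138	0.0759744
18	0.248318	0.0656649	0.14067	0.0419836	0.0705464
18.5	0.241709	0.0607299	0.140804	0.0401751	0.0657006
19	0.235684	0.0562906	0.140915	0.0384785	0.0613537
19.5	0.230168	0.0522791	0.141004	0.0368852	0.0574371
20	0.2251	0.0486392	0.141074	0.0353871	0.0538942
20.5	0.220698	0.0453261	0.141395	0.0339769	0.050697
21	0.216651	0.0423095	0.141693	0.0326481	0.0477968
21.5	0.212927	0.0395632	0.14197	0.0313945	0.0451672
22	0.2095	0.0370627	0.142226	0.0302107	0.0427839
22.5	0.206342	0.0347857	0.142464	0.0290918	0.040624
23	0.203429	0.0327113	0.142685	0.028033	0.0386669
23.5	0.200739	0.0308206	0.142889	0.0270302	0.0368935
24	0.198253	0.0290965	0.143077	0.0260796	0.0352866
24.5	0.195952	0.0275234	0.143251	0.0251777	0.0338305
25	0.19382	0.0260873	0.143411	0.0243216	0.0325111
25.5	0.191844	0.0247754	0.143558	0.0235113	0.0313155
26	0.190011	0.0235762	0.143692	0.0227438	0.0302324
26.5	0.188309	0.0224795	0.143814	0.0220157	0.0292514
27	0.186725	0.021476	0.143924	0.021324	0.0283631
27.5	0.185249	0.0205574	0.144025	0.0206662	0.0275593
28	0.183872	0.0197161	0.144116	0.0200398	0.0268323
28.5	0.182585	0.0189455	0.144197	0.0194427	0.0261755
29	0.181382	0.0182395	0.14427	0.0188729	0.0255828
29.5	0.180256	0.0175926	0.144335	0.0183287	0.0250486
30	0.1792	0.017	0.144391	0.0178086	0.0245682
30.5	0.178089	0.0164568	0.144321	0.0173109	0.0241303
31	0.177038	0.0159577	0.144246	0.0168345	0.0237358
31.5	0.176042	0.0154975	0.144166	0.0163781	0.0233795
32	0.175095	0.0150716	0.144082	0.0159405	0.0230569
32.5	0.174192	0.0146764	0.143995	0.0155207	0.0227643
33	0.173329	0.0143083	0.143903	0.0151177	0.0224983
33.5	0.172503	0.0139645	0.143808	0.0147307	0.0222558
34	0.171711	0.0136423	0.14371	0.0143587	0.0220343
34.5	0.170949	0.0133394	0.143608	0.0140011	0.0218314
35	0.170215	0.0130539	0.143504	0.013657	0.0216452
35.5	0.169506	0.0127838	0.143397	0.0133258	0.0214738
36	0.168821	0.0125276	0.143287	0.0130069	0.0213157
36.5	0.168158	0.012284	0.143175	0.0126997	0.0211695
37	0.167515	0.0120515	0.14306	0.0124035	0.0210337
37.5	0.16689	0.0118291	0.142943	0.012118	0.0209074
38	0.166283	0.0116158	0.142825	0.0118425	0.0207896
38.5	0.165691	0.0114106	0.142704	0.0115766	0.0206792
39	0.165114	0.0112127	0.142581	0.0113199	0.0205756
39.5	0.164551	0.0110215	0.142457	0.011072	0.0204779
40	0.164	0.0108362	0.142331	0.0108325	0.0203855
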