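# energy_keV	mu_total	mu_pe	mu_incoh	mu_coh	mu_en
1	3605.68	3604.31	0.0134645	1.36207	3605.32
1.2	2199.08	2197.74	0.0186804	1.31937	2198.86
1.4	1441.75	1440.46	0.0244256	1.27225	1441.61
1.6	994.389	993.136	0.0305461	1.22195	994.289
1.8	713.075	711.868	0.0368962	1.16965	713.004
2	528.037	526.877	0.0433443	1.11642	527.984
2.2	401.66	400.547	0.0497767	1.06321	401.62
2.4	312.449	311.382	0.0561	1.01078	312.418
2.6	247.685	246.663	0.0622406	0.959732	247.656
2.8	199.54	198.561	0.0681444	0.910532	199.513
3	163.014	162.077	0.0737739	0.863496	162.989
3.2	134.814	133.916	0.0791065	0.818819	134.785
3.2029	134.454	133.556	0.0791793	0.818172	134.423
3.2031	148.437	147.539	0.0791843	0.818128	146.889
3.4	124.717	123.856	0.0841312	0.776605	123.387
3.6	105.515	104.689	0.0888463	0.736877	104.341
3.8	90.0568	89.2639	0.0932569	0.699604	88.996
4	77.4773	76.7152	0.0973732	0.664713	76.5082
4.2	67.1359	66.4026	0.101208	0.632102	66.2422
4.4	58.5455	57.839	0.104777	0.601653	57.7149
4.6	51.3415	50.6602	0.108097	0.573241	50.5642
4.8	45.2491	44.5912	0.111182	0.546735	44.5173
5	40.0581	39.422	0.11405	0.522007	39.3656
5.2	35.6078	34.9921	0.116717	0.498931	34.9495
5.4	31.7796	31.183	0.119196	0.477389	31.1514
5.6	28.477	27.8982	0.121503	0.457266	27.8753
5.8	25.6189	25.0568	0.123649	0.438458	25.0409
6	23.1379	22.5914	0.125648	0.420865	22.5811
6.2	20.9763	20.4444	0.127511	0.404395	20.4387
6.4	19.0833	18.5651	0.129248	0.388962	18.563
6.6	17.4171	16.9117	0.130868	0.374488	16.9125
6.8	15.9434	15.4501	0.132381	0.3609	15.4532
7	14.6342	14.1523	0.133795	0.348131	14.1573
7.2	13.4666	12.9953	0.135117	0.336118	13.0018
7.4	12.4212	11.9601	0.136355	0.324804	11.9677
7.6	11.4821	11.0305	0.137514	0.314137	11.0389
7.8	10.6357	10.193	0.138601	0.304069	10.2022
8	9.87055	9.43637	0.139622	0.294555	9.446
8.2	9.17697	8.75084	0.14058	0.285553	8.75833
8.4	8.5469	8.12839	0.14148	0.277028	8.13404
8.6	7.97335	7.56208	0.142328	0.268943	7.56616
8.8	7.45025	7.04586	0.143126	0.261267	7.0486
9	6.97226	6.57441	0.143878	0.253972	6.57601
9.2	6.53471	6.14309	0.144588	0.24703	6.14372
9.4	6.13346	5.74779	0.145258	0.240418	5.7476
9.6	5.76489	5.38489	0.145891	0.234111	5.38402
9.8	5.42578	5.0512	0.14649	0.228091	5.04977
10	5.11328	4.74389	0.147056	0.222337	4.742
10.5	4.43255	4.0752	0.148346	0.209007	4.07539
11	3.87058	3.5241	0.149476	0.197003	3.52586
11.5	3.40279	3.06619	0.150471	0.186131	3.06915
12	3.01045	2.68286	0.151349	0.176233	2.68674
12.5	2.67905	2.35974	0.152125	0.16718	2.36432
13	2.3973	2.08562	0.152814	0.158864	2.09074
13.5	2.1563	1.85168	0.153426	0.151197	1.85723
14	1.94899	1.65092	0.153969	0.144103	1.6568
14.5	1.76971	1.47774	0.154452	0.13752	1.48389
15	1.61391	1.32763	0.154881	0.131392	1.334
15.5	1.47785	1.19692	0.155262	0.125674	1.20303
16	1.3585	1.08258	0.155599	0.120327	1.0885
16.5	1.25334	0.982129	0.155897	0.115315	0.987911
17	1.16031	0.893536	0.15616	0.11061	0.899225
17.5	1.07768	0.815106	0.15639	0.106184	0.820737
18	1.00403	0.745426	0.15659	0.102015	0.751031
18.5	0.938161	0.683317	0.156763	0.0980815	0.688919
19	0.879059	0.627782	0.156911	0.0943661	0.633403
19.5	0.825868	0.577979	0.157036	0.0908521	0.583636
20	0.777857	0.533192	0.15714	0.0875249	0.5389
20.5	0.734706	0.49281	0.157525	0.0843713	0.498663
21	0.695577	0.456314	0.157884	0.0813792	0.46231
21.5	0.660013	0.423254	0.158221	0.0785378	0.429392
22	0.627615	0.393244	0.158535	0.0758371	0.399523
22.5	0.598041	0.365945	0.158828	0.073268	0.372364
23	0.570987	0.341063	0.159101	0.0708223	0.347621
23.5	0.54619	0.318342	0.159356	0.0684922	0.325037
24	0.523419	0.297554	0.159594	0.0662706	0.304387
24.5	0.50247	0.278504	0.159815	0.0641512	0.285472
25	0.483166	0.261015	0.160021	0.062131	0.268119
25.5	0.465372	0.244933	0.160208	0.060231	0.252171
26	0.448947	0.230122	0.160379	0.0584457	0.237494
26.5	0.433759	0.216461	0.160534	0.0567639	0.223966
27	0.419692	0.203842	0.160674	0.0551762	0.211478
27.5	0.406645	0.192169	0.160802	0.0536742	0.199936
28	0.394523	0.181356	0.160916	0.0522507	0.189254
28.5	0.383246	0.171327	0.16102	0.0508993	0.179354
29	0.372739	0.162013	0.161112	0.0496144	0.170169
29.5	0.362938	0.153352	0.161195	0.048391	0.161636
30	0.353781	0.145289	0.161267	0.0472247	0.1537
30.5	0.345083	0.137774	0.161198	0.0461115	0.146303
31	0.336931	0.130761	0.161122	0.0450479	0.139409
31.5	0.329281	0.12421	0.16104	0.0440305	0.132975
32	0.322094	0.118083	0.160954	0.0430566	0.126964
32.5	0.315333	0.112348	0.160862	0.0421234	0.121344
33	0.308967	0.106972	0.160766	0.0412285	0.116083
33.5	0.302965	0.101929	0.160666	0.0403697	0.111154
34	0.2973	0.097194	0.160562	0.0395449	0.106532
34.5	0.291949	0.0927435	0.160453	0.0387523	0.102195
35	0.286889	0.0885568	0.160342	0.0379901	0.0981197
35.5	0.282098	0.0846147	0.160227	0.0372566	0.0942887
36	0.277559	0.0808999	0.160109	0.0365505	0.0906842
36.5	0.273255	0.0773962	0.159988	0.0358703	0.0872901
37	0.269168	0.074089	0.159864	0.0352148	0.0840919
37.5	0.265286	0.0709649	0.159738	0.0345827	0.0810759
38	0.261594	0.0680114	0.15961	0.0339728	0.0782299
38.5	0.25808	0.0652172	0.159478	0.0333842	0.0755424
39	0.254733	0.0625717	0.159345	0.0328158	0.0730029
39.5	0.251542	0.0600653	0.15921	0.0322668	0.0706017
40	0.248498	0.057689	0.159073	0.0317362	0.06833
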