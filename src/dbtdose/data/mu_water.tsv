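# energy_keV	mu_total	mu_pe	mu_incoh	mu_coh	mu_en
1	4077.2	4075.81	0.0156988	1.37228	4076.75
1.2	2512.02	2510.67	0.021794	1.33424	2511.73
1.4	1660.21	1658.89	0.0284666	1.29197	1660
1.6	1152.21	1150.92	0.0355331	1.24648	1152.05
1.8	830.274	829.033	0.0428254	1.19875	830.148
2	617.261	616.061	0.0501965	1.1497	617.155
2.2	471.089	469.931	0.0575234	1.10012	470.998
2.4	367.482	366.366	0.0647082	1.05072	367.401
2.6	291.995	290.921	0.0716758	1.00205	291.922
2.8	235.699	234.666	0.0783722	0.954578	235.632
3	192.87	191.876	0.0847611	0.908647	192.807
3.2	159.721	158.765	0.0908205	0.864505	159.661
3.4	133.69	132.771	0.0965402	0.822319	133.633
3.6	112.986	112.102	0.101919	0.782186	112.872
3.8	96.3255	95.4744	0.106962	0.744148	96.1305
4	82.7776	81.9577	0.111679	0.708204	82.5211
4.2	71.6506	70.8602	0.116083	0.674319	71.3475
4.4	62.4174	61.6547	0.12019	0.642436	62.0789
4.6	54.6826	53.9461	0.124017	0.612477	54.3174
4.8	48.1484	47.4365	0.127579	0.584356	47.7632
5	42.587	41.8981	0.130895	0.557978	42.187
5.2	37.8243	37.157	0.133981	0.533245	37.4134
5.4	33.7311	33.0841	0.136853	0.510058	33.3126
5.6	30.2025	29.5747	0.139527	0.48832	29.7791
5.8	27.151	26.5411	0.142016	0.467935	26.7248
6	24.5036	23.9104	0.144336	0.448813	24.0762
6.2	22.1982	21.6208	0.146499	0.430866	21.7709
6.4	20.1802	19.6177	0.148516	0.414011	19.7541
6.6	18.4046	17.856	0.150399	0.39817	17.9805
6.8	16.8348	16.2994	0.152157	0.383273	16.4132
7	15.4408	14.9178	0.153801	0.369249	15.0222
7.2	14.1979	13.6865	0.155339	0.356038	13.7826
7.4	13.0854	12.5851	0.156779	0.34358	12.6737
7.6	12.0863	11.5964	0.158127	0.331821	11.6783
7.8	11.1861	10.706	0.159392	0.320713	10.7818
8	10.3724	9.90164	0.160579	0.310208	9.97204
8.2	9.63509	9.17313	0.161693	0.300266	9.236
8.4	8.96553	8.51195	0.16274	0.290846	8.56817
8.6	8.35639	7.91076	0.163724	0.281913	7.96112
8.8	7.80123	7.36314	0.16465	0.273435	7.40833
9	7.29436	6.86346	0.165522	0.26538	6.90406
9.2	6.83082	6.40675	0.166344	0.257721	6.44329
9.4	6.40619	5.98864	0.167118	0.250432	6.02157
9.6	6.01659	5.60526	0.167848	0.243488	5.63498
9.8	5.65859	5.25318	0.168537	0.236868	5.28005
10	5.32911	4.92937	0.169188	0.230551	4.9537
10.5	4.61303	4.2264	0.170662	0.215964	4.2485
11	4.02359	3.64876	0.171943	0.202897	3.66898
11.5	3.53417	3.16998	0.17306	0.191134	3.1886
12	3.12452	2.76999	0.174035	0.180494	2.78726
12.5	2.77912	2.4334	0.174888	0.170828	2.44951
13	2.48589	2.14825	0.175635	0.162007	2.16338
13.5	2.2354	1.90518	0.17629	0.153926	1.91946
14	2.02015	1.69679	0.176863	0.146494	1.71035
14.5	1.83418	1.51718	0.177365	0.139635	1.5301
15	1.67267	1.36159	0.177804	0.133284	1.37398
15.5	1.53175	1.22618	0.178187	0.127385	1.23766
16	1.40822	1.10781	0.17852	0.121891	1.11856
16.5	1.29948	1.00391	0.178809	0.116761	1.01405
17	1.20337	0.91235	0.179057	0.11196	0.922002
17.5	1.1181	0.831372	0.179269	0.107456	0.840626
18	1.04218	0.759505	0.179449	0.103224	0.768437
18.5	0.974351	0.695513	0.179598	0.0992394	0.704191
19	0.913561	0.638359	0.17972	0.0954816	0.646837
19.5	0.858913	0.587162	0.179818	0.0919324	0.595487
20	0.809643	0.541175	0.179893	0.0885756	0.549385
20.5	0.765368	0.499758	0.180213	0.0853967	0.50797
21	0.725254	0.462363	0.180508	0.0823828	0.470594
21.5	0.68882	0.428518	0.18078	0.0795221	0.436782
22	0.655651	0.397817	0.181029	0.0768043	0.406127
22.5	0.625385	0.369907	0.181258	0.0742197	0.378272
23	0.597708	0.344481	0.181467	0.0717598	0.352912
23.5	0.572348	0.321272	0.181659	0.0694167	0.329777
24	0.549063	0.300047	0.181833	0.0671831	0.308632
24.5	0.527644	0.2806	0.181991	0.0650525	0.289272
25	0.507907	0.262752	0.182133	0.0630221	0.271515
25.5	0.489714	0.246343	0.182259	0.0611122	0.255203
26	0.472919	0.231234	0.182368	0.0593176	0.240194
26.5	0.457388	0.217299	0.182462	0.0576274	0.226363
27	0.443002	0.204428	0.182542	0.0560319	0.213599
27.5	0.429656	0.192524	0.18261	0.054523	0.201804
28	0.417256	0.181498	0.182665	0.0530935	0.190889
28.5	0.405718	0.171271	0.18271	0.0517369	0.180776
29	0.394966	0.161775	0.182744	0.0504476	0.171394
29.5	0.384934	0.152945	0.182769	0.0492206	0.162681
30	0.375561	0.144725	0.182784	0.0480514	0.154579
30.5	0.366674	0.137065	0.182673	0.0469361	0.14703
31	0.358345	0.129918	0.182555	0.045871	0.139996
31.5	0.350529	0.123244	0.182432	0.0448528	0.133435
32	0.343188	0.117005	0.182305	0.0438786	0.127309
32.5	0.336284	0.111167	0.182172	0.0429456	0.121585
33	0.329785	0.105699	0.182035	0.0420514	0.116231
33.5	0.323661	0.100573	0.181894	0.0411937	0.11122
34	0.317883	0.0957636	0.181749	0.0403705	0.106525
34.5	0.312428	0.0912472	0.181601	0.0395797	0.102124
35	0.307271	0.0870024	0.181449	0.0388197	0.0979935
35.5	0.302393	0.0830095	0.181294	0.0380888	0.0941152
36	0.297773	0.0792507	0.181137	0.0373854	0.0904708
36.5	0.293394	0.0757093	0.180976	0.0367082	0.0870436
37	0.289239	0.0723704	0.180813	0.0360558	0.0838186
37.5	0.285294	0.0692199	0.180648	0.035427	0.0807818
38	0.281546	0.0662452	0.18048	0.0348207	0.0779203
38.5	0.27798	0.0634343	0.18031	0.0342357	0.0752224
39	0.274586	0.0607764	0.180138	0.0336711	0.072677
39.5	0.271352	0.0582615	0.179965	0.033126	0.0702743
40	0.268269	0.0558802	0.179789	0.0325993	0.0680048
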