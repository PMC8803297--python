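# energy_keV	mu_total	mu_pe	mu_incoh	mu_coh	mu_en
1	2211	2209.9	0.0182081	1.07889	2210.78
1.2	1321.14	1320.08	0.0250221	1.03311	1321
1.4	852.801	851.785	0.0323171	0.984016	852.716
1.6	581.738	580.765	0.0398547	0.933196	581.68
1.8	413.676	412.747	0.0474296	0.88203	413.635
2	303.9	303.013	0.0548766	0.831632	303.87
2.2	229.224	228.379	0.0620714	0.782845	229.201
2.4	176.817	176.012	0.0689274	0.736259	176.799
2.6	139.065	138.297	0.0753906	0.692248	139.051
2.8	111.245	110.512	0.0814329	0.651009	111.233
3	90.33	89.6303	0.0870462	0.612607	90.246
3.2	74.3239	73.6546	0.0922364	0.577011	74.1607
3.4	61.868	61.2268	0.097019	0.544123	61.6477
3.6	52.0295	51.4143	0.101416	0.513804	51.7679
3.8	44.1557	43.5643	0.105451	0.485892	43.8641
4	37.78	37.2106	0.109152	0.460216	37.4669
4.2	32.5634	32.0143	0.112544	0.436601	32.2349
4.4	28.2561	27.7256	0.115654	0.414875	27.9168
4.6	24.6699	24.1565	0.118505	0.394878	24.3234
4.8	21.6615	21.1639	0.121122	0.376454	21.3103
5	19.12	18.637	0.123526	0.359461	18.7661
5.2	16.9591	16.4896	0.125735	0.343768	16.604
5.4	15.1106	14.6535	0.127769	0.329254	14.7554
5.6	13.5203	13.0749	0.129644	0.315809	13.166
5.8	12.1451	11.7104	0.131375	0.303332	11.7922
6	10.95	10.5253	0.132975	0.291735	10.5991
6.2	9.90672	9.49132	0.134457	0.280935	9.55807
6.4	8.99215	8.58546	0.13583	0.270858	8.64606
6.6	8.18729	7.78874	0.137106	0.261439	7.84393
6.8	7.47635	7.08544	0.138293	0.252619	7.13587
7	6.84618	6.46244	0.139399	0.244344	6.50866
7.2	6.28577	5.90877	0.140432	0.236566	5.95126
7.4	5.78582	5.41519	0.141396	0.229242	5.45435
7.6	5.3385	4.97386	0.142299	0.222334	5.01007
7.8	4.93712	4.57817	0.143145	0.215806	4.61172
8	4.576	4.22243	0.14394	0.209628	4.25361
8.2	4.25026	3.90181	0.144686	0.203771	3.92973
8.4	3.9557	3.6121	0.145389	0.19821	3.63718
8.6	3.68868	3.34971	0.146051	0.192922	3.37229
8.8	3.44607	3.11151	0.146676	0.187885	3.13189
9	3.22516	2.89481	0.147266	0.183082	2.91326
9.2	3.02358	2.69726	0.147824	0.178494	2.714
9.4	2.83927	2.51681	0.148352	0.174107	2.53204
9.6	2.67043	2.35167	0.148852	0.169906	2.36556
9.8	2.51547	2.20026	0.149327	0.165879	2.21297
10	2.373	2.06121	0.149777	0.162013	2.07287
10.5	2.0638	1.76	0.150808	0.15299	1.77078
11	1.80988	1.51339	0.151719	0.144772	1.52344
11.5	1.59961	1.30984	0.152528	0.137244	1.31928
12	1.42411	1.14054	0.153248	0.130314	1.14949
12.5	1.27654	0.998747	0.15389	0.123908	1.00728
13	1.15162	0.879195	0.154463	0.117964	0.887384
13.5	1.04518	0.777775	0.154976	0.112431	0.785687
14	0.95394	0.691239	0.155435	0.107266	0.698926
14.5	0.875279	0.617001	0.155844	0.102433	0.624507
15	0.8071	0.552987	0.15621	0.0979029	0.56035
15.5	0.747699	0.497516	0.156535	0.0936482	0.504586
16	0.695664	0.449194	0.156823	0.0896466	0.456039
16.5	0.649846	0.40689	0.157078	0.0858783	0.413565
17	0.60931	0.369682	0.157302	0.0823256	0.376233
17.5	0.573287	0.336817	0.157497	0.0789732	0.343281
18	0.541143	0.307671	0.157665	0.0758071	0.314079
18.5	0.51235	0.281727	0.157809	0.0728147	0.288106
19	0.486467	0.258553	0.15793	0.0699846	0.264924
19.5	0.463122	0.237786	0.158029	0.0673063	0.244168
20	0.442	0.219121	0.158109	0.0647703	0.225529
20.5	0.423138	0.202297	0.158473	0.0623678	0.208786
21	0.406008	0.187105	0.158812	0.0600906	0.19368
21.5	0.390421	0.173362	0.159128	0.0579309	0.180028
22	0.376211	0.160907	0.159422	0.0558818	0.16767
22.5	0.363234	0.149601	0.159697	0.0539366	0.156464
23	0.35136	0.13932	0.159951	0.0520891	0.146286
23.5	0.340477	0.129955	0.160188	0.0503336	0.137028
24	0.330484	0.121411	0.160408	0.0486644	0.128594
24.5	0.321292	0.113604	0.160611	0.0470767	0.120898
25	0.312825	0.106459	0.160799	0.0455673	0.113865
25.5	0.305026	0.09991	0.16097	0.0441464	0.10743
26	0.297832	0.0938978	0.161125	0.0428089	0.101533
26.5	0.291183	0.0883705	0.161266	0.0415469	0.0961222
27	0.285029	0.0832818	0.161393	0.0403535	0.0911504
27.5	0.279322	0.0785904	0.161509	0.0392228	0.0865764
28	0.274021	0.0742592	0.161612	0.0381495	0.0823631
28.5	0.269089	0.0702554	0.161705	0.0371292	0.0784775
29	0.264495	0.0665493	0.161788	0.0361578	0.0748899
29.5	0.260207	0.0631145	0.161861	0.0352317	0.0715737
30	0.2562	0.0599272	0.161925	0.0343478	0.068505
30.5	0.252315	0.0569656	0.161846	0.0335032	0.0656546
31	0.248667	0.0542093	0.161762	0.0326952	0.0630092
31.5	0.245234	0.0516395	0.161673	0.0319217	0.0605503
32	0.242	0.0492399	0.161579	0.0311804	0.0582611
32.5	0.238946	0.0469956	0.161481	0.0304695	0.0561271
33	0.236059	0.0448936	0.161378	0.0297871	0.0541348
33.5	0.233325	0.0429218	0.161272	0.0291317	0.0522726
34	0.230733	0.0410698	0.161161	0.0285018	0.0505296
34.5	0.228272	0.0393281	0.161048	0.027896	0.0488965
35	0.225932	0.0376878	0.160931	0.0273131	0.0473644
35.5	0.223704	0.0361414	0.160811	0.0267517	0.0459256
36	0.221581	0.0346817	0.160688	0.026211	0.044573
36.5	0.219554	0.0333023	0.160562	0.0256898	0.0433002
37	0.217619	0.0319974	0.160434	0.0251871	0.0421014
37.5	0.215767	0.0307617	0.160303	0.0247022	0.0409713
38	0.213995	0.0295904	0.160171	0.0242341	0.039905
38.5	0.212297	0.0284791	0.160035	0.023782	0.038898
39	0.210667	0.0274237	0.159898	0.0233453	0.0379465
39.5	0.209103	0.0264205	0.159759	0.0229233	0.0370465
40	0.2076	0.0254661	0.159619	0.0225153	0.0361948
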