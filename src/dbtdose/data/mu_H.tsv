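# energy_keV	mu_total	mu_pe	mu_incoh	mu_coh	mu_en
1	7.217	6.81983	0.0503949	0.346774	6.86674
1.2	4.10091	3.70391	0.0690096	0.327987	3.7295
1.4	2.60528	2.2085	0.0887617	0.308017	2.2239
1.6	1.80579	1.40927	0.108959	0.28756	1.41928
1.8	1.34328	0.947057	0.129018	0.267206	0.954011
2	1.059	0.663101	0.148482	0.247417	0.668233
2.2	0.875576	0.480026	0.167019	0.228532	0.484038
2.4	0.752421	0.357236	0.184415	0.210771	0.360551
2.6	0.66693	0.27212	0.200552	0.194258	0.275004
2.8	0.605878	0.21145	0.215387	0.179041	0.214076
3	0.5612	0.167157	0.228935	0.165108	0.16964
3.2	0.527795	0.134136	0.241246	0.152413	0.136557
3.4	0.502328	0.109051	0.252395	0.140882	0.111466
3.6	0.482577	0.0896777	0.26247	0.130429	0.0921266
3.8	0.467021	0.0744952	0.271563	0.120962	0.0770072
4	0.4546	0.0624427	0.279766	0.112392	0.0650389
4.2	0.444562	0.0527669	0.287166	0.104629	0.0554634
4.4	0.436367	0.0449297	0.293847	0.0975908	0.0477384
4.6	0.429616	0.0385305	0.299884	0.0912019	0.0414603
4.8	0.424005	0.0332655	0.305346	0.085393	0.0363233
5	0.4193	0.0289022	0.310296	0.0801019	0.0320933
5.2	0.415321	0.02526	0.314788	0.075273	0.0285881
5.4	0.411921	0.0221933	0.318871	0.0708569	0.0256614
5.6	0.408989	0.01959	0.32259	0.0668098	0.0232002
5.8	0.406438	0.0173638	0.325981	0.0630931	0.0211177
6	0.4042	0.0154475	0.32908	0.0596727	0.0193462
6.2	0.402223	0.013789	0.331915	0.0565185	0.0178332
6.4	0.400467	0.0123493	0.334514	0.0536041	0.0165395
6.6	0.398901	0.0110962	0.336899	0.050906	0.0154327
6.8	0.397497	0.0100026	0.339091	0.0484035	0.0144856
7	0.396231	0.00904569	0.341107	0.0460783	0.0136751
7.2	0.395085	0.00820609	0.342965	0.0439143	0.0129819
7.4	0.394042	0.00746743	0.344678	0.0418969	0.0123895
7.6	0.393088	0.00681584	0.346259	0.0400133	0.0118838
7.8	0.392211	0.00623951	0.347719	0.038252	0.0114531
8	0.3914	0.00572844	0.349069	0.0366027	0.0110873
8.2	0.390647	0.00527364	0.350317	0.0350561	0.0107743
8.4	0.389943	0.00486611	0.351473	0.033604	0.0105083
8.6	0.38928	0.00449827	0.352543	0.0322389	0.0102817
8.8	0.388652	0.00416415	0.353534	0.0309539	0.0100884
9	0.388054	0.00385892	0.354452	0.0297431	0.00992366
9.2	0.387482	0.00357871	0.355302	0.0286008	0.00978346
9.4	0.386933	0.00332038	0.356091	0.0275219	0.00966466
9.6	0.386404	0.00308136	0.356821	0.026502	0.00956469
9.8	0.385894	0.00285954	0.357498	0.0255368	0.00948142
10	0.3854	0.00265319	0.358124	0.0246225	0.00941309
10.5	0.38423	0.00219868	0.359494	0.0225374	0.00930792
11	0.383148	0.00182644	0.36062	0.0207023	0.00928139
11.5	0.382143	0.00152636	0.361538	0.0190791	0.00932353
12	0.381203	0.00128669	0.36228	0.0176368	0.00942272
12.5	0.380317	0.00109626	0.362871	0.0163496	0.00956784
13	0.379474	0.000945347	0.363332	0.0151964	0.00974929
13.5	0.378667	0.000825939	0.363682	0.0141593	0.00995911
14	0.377889	0.000731614	0.363934	0.0132234	0.0101909
14.5	0.377135	0.00065733	0.364101	0.0123761	0.0104398
15	0.3764	0.000599181	0.364194	0.0116066	0.0107019
15.5	0.375682	0.000553664	0.364222	0.0109059	0.0109698
16	0.374975	0.000516405	0.364193	0.0102661	0.011243
16.5	0.374277	0.000484028	0.364113	0.00968029	0.0115183
17	0.373585	0.000454236	0.363988	0.0091427	0.0117933
17.5	0.372897	0.000425485	0.363823	0.00864822	0.0120666
18	0.372212	0.000396791	0.363623	0.0081924	0.0123372
18.5	0.37153	0.000367606	0.363391	0.00777134	0.0126047
19	0.370851	0.000337733	0.363131	0.00738163	0.0128689
19.5	0.370174	0.000307253	0.362847	0.00702025	0.01313
20	0.3695	0.000276455	0.362539	0.00668455	0.0133882
20.5	0.368829	0.000245931	0.362211	0.00637217	0.0136461
21	0.368163	0.000216797	0.361865	0.00608101	0.013903
21.5	0.367502	0.000189883	0.361503	0.00580921	0.0141598
22	0.366847	0.000165617	0.361126	0.00555511	0.0144168
22.5	0.366197	0.000144142	0.360736	0.0053172	0.0146744
23	0.365553	0.000125402	0.360334	0.00509415	0.0149325
23.5	0.364915	0.000109225	0.359921	0.00488476	0.0151908
24	0.364281	9.5375e-05	0.359498	0.00468793	0.0154493
24.5	0.363653	8.35899e-05	0.359067	0.0045027	0.0157077
25	0.363029	7.36094e-05	0.358627	0.00432817	0.0159658
25.5	0.36241	6.51877e-05	0.358181	0.00416354	0.0162232
26	0.361795	5.81026e-05	0.357728	0.00400808	0.01648
26.5	0.361183	5.21579e-05	0.35727	0.00386112	0.0167357
27	0.360576	4.71844e-05	0.356806	0.00372206	0.0169904
27.5	0.359971	4.30382e-05	0.356338	0.00359035	0.017244
28	0.359371	3.95985e-05	0.355866	0.00346547	0.0174962
28.5	0.358773	3.67652e-05	0.35539	0.00334697	0.017747
29	0.358179	3.44562e-05	0.35491	0.00323443	0.0179965
29.5	0.357588	3.26053e-05	0.354428	0.00312744	0.0182444
30	0.357	3.11599e-05	0.353943	0.00302566	0.0184908
30.5	0.356415	3.00736e-05	0.353456	0.00292875	0.0187357
31	0.355833	2.92896e-05	0.352967	0.0028364	0.0189789
31.5	0.355253	2.87596e-05	0.352476	0.00274835	0.0192206
32	0.354677	2.84462e-05	0.351984	0.00266432	0.0194607
32.5	0.354103	2.83203e-05	0.35149	0.00258407	0.0196991
33	0.353532	2.8359e-05	0.350996	0.00250739	0.0199359
33.5	0.352963	2.85438e-05	0.3505	0.00243407	0.0201711
34	0.352397	2.88597e-05	0.350004	0.0023639	0.0204046
34.5	0.351834	2.92942e-05	0.349508	0.00229673	0.0206366
35	0.351273	2.98369e-05	0.349011	0.00223237	0.0208669
35.5	0.350715	3.04785e-05	0.348513	0.00217067	0.0210957
36	0.350159	3.12107e-05	0.348016	0.0021115	0.0213228
36.5	0.349605	3.2026e-05	0.347519	0.00205471	0.0215484
37	0.349055	3.2917e-05	0.347022	0.00200017	0.0217723
37.5	0.348506	3.38766e-05	0.346525	0.00194778	0.0219948
38	0.34796	3.48976e-05	0.346028	0.00189742	0.0222156
38.5	0.347417	3.59728e-05	0.345532	0.00184898	0.0224349
39	0.346875	3.70945e-05	0.345036	0.00180238	0.0226527
39.5	0.346337	3.82548e-05	0.344541	0.00175752	0.022869
40	0.3458	3.94455e-05	0.344046	0.00171431	0.0230837
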