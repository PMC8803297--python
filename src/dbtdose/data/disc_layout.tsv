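# id	x_cm	y_cm
1	-8.0	2.0
2	-4.0	2.0
3	0.0	2.0
4	4.0	2.0
5	8.0	2.0
6	-8.0	6.0
7	-4.0	6.0
8	0.0	6.0
9	4.0	6.0
10	8.0	6.0
11	-8.0	10.0
12	-4.0	10.0
13	0.0	10.0
14	4.0	10.0
15	8.0	10.0
16	-8.0	14.0
17	-4.0	14.0
18	0.0	14.0
19	4.0	14.0
20	8.0	14.0
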