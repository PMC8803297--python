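# Calibration factors (C) of the OSLDs and AGD conversion factors per beam
# quality (W/Rh).  g: incident air kerma -> AGD at 50% glandularity;
# c: glandularity correction; s: target/filter correction; T: tube-motion
# correction (3D acquisitions only).
kvp	C	g	c	s	T
25	1.053	0.540	0.914	1.042	0.979
28	1.005	0.306	1.035	1.042	0.970
34	1.021	0.169	1.251	1.042	0.962
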