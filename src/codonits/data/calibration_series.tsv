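fraction_pct	main_signal	s_mean_pct	s_sd_pct	n_mean_pct	n_sd_pct	significant
10	C	11.54	1.46	10.82	0.98	False
15	C	14.82	1.16	10.64	1.13	True
20	C	21.08	2.23	10.66	1.07	True
30	C	29.14	1.65	8.92	1.18	True
40	C	39.60	1.87	9.02	1.19	True
50	C	47.72	1.37	8.84	1.16	True
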