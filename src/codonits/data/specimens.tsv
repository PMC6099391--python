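voucher	species	locality	locality_no	altitude_m	date	its_type	its_type_table4	ratio122_mean	ratio122_sd	ratio226_mean	ratio226_sd
CP01	C. pilosula	Liancai, Longde, Guyuan, Ningxia, China	1	1760	2016-07-20	P1	P1	33.46	1.29	46.89	1.35
CP02	C. pilosula	Kezhai, Longxi, Dingxi, Gansu, China	2	2220	2016-10-25	P2	P2			33.49	1.55
CP03	C. pilosula	Xiaozhai, Minxian, Dingxi, Gansu, China	3	2550	2016-10-25	P1	P1	37.47	1.47	37.07	0.50
CP04	C. pilosula	Weixin, Minxian, Dingxi, Gansu, China	4	2225	2016-10-25	P1	P1	36.14	1.73	39.39	1.17
CP05	C. pilosula	Xijiang, Minxian, Dingxi, Gansu, China	5	2254	2016-10-25	P1	P1	48.33	1.56	25.14	2.52
CP06	C. pilosula	Meichuan, Minxian, Dingxi, Gansu, China	6	2328	2016-10-25	P1	P1	35.23	1.31	39.18	1.52
CP07	C. pilosula	Minyang, Minxian, Dingxi, Gansu, China	7	2305	2016-10-25	P1	P1	33.25	0.70	41.59	0.45
CP08	C. pilosula	Chabu, Minxian, Dingxi, Gansu, China	8	2313	2016-10-25	P1	P1	44.77	1.09	39.70	1.62
CP09	C. pilosula	Zhongzhai, Minxian, Dingxi, Gansu, China	10	2381	2016-10-25	P1	P1	31.90	1.17	33.57	2.13
CP10	C. pilosula	Hadapu, Tanchang, Longnan, Gansu, China	11	2281	2016-10-28	P3	P3	32.72	1.48	47.79	1.77
CP11	C. pilosula	Hadapu, Tanchang, Longnan, Gansu, China		2250	2016-10-28	P1	P1	40.86	1.71	29.05	2.04
CP12	C. pilosula	Hadapu, Tanchang, Longnan, Gansu, China		2238	2016-10-28	P1	P1	38.34	1.26	39.92	2.39
CP13	C. pilosula	Hadapu, Tanchang, Longnan, Gansu, China		2233	2016-10-28	P1	P1	35.94	0.98	40.33	3.32
CP14	C. pilosula	Hadapu, Tanchang, Longnan, Gansu, China		2271	2016-10-28	P1	P1	44.52	0.72	38.14	1.68
CP15	C. pilosula	Awu, Tanchang, Longnan, Gansu, China	12	2421	2016-10-28	P1	P1	35.05	1.40	43.61	2.30
CP16	C. pilosula	Pangjia, Tanchang, Longnan, Gansu, China	13	2503	2016-10-28	P1	P1	30.65	0.99	32.98	2.03
CP17	C. pilosula	Pangjia, Tanchang, Longnan, Gansu, China		2368	2016-10-28	P1	P1	32.57	0.80	28.64	0.82
CP18	C. pilosula	Pangjia, Tanchang, Longnan, Gansu, China		2390	2016-10-28	P1	P1	45.63	0.93	32.35	2.46
CP19	C. pilosula	Lichuan, Tanchang, Longnan, Gansu, China	14	2255	2016-10-28	P1	P1	39.53	3.48	40.20	2.11
CP20	C. pilosula	Lichuan, Tanchang, Longnan, Gansu, China		2286	2016-10-28	P1	P1	32.24	0.63	37.79	1.06
CP21	C. pilosula	Lichuan, Tanchang, Longnan, Gansu, China		2388	2016-10-28	P1	P1	40.25	0.21	40.62	1.27
CP22	C. pilosula	Lichuan, Tanchang, Longnan, Gansu, China		2475	2016-10-28	P1	P1	35.93	0.35	37.99	1.30
CP23	C. pilosula	Lichuan, Tanchang, Longnan, Gansu, China		2314	2016-10-28	P1	P1	39.33	0.94	33.61	1.03
CP24	C. pilosula	Lichuan, Tanchang, Longnan, Gansu, China		2320	2016-10-28	P1	P1	36.48	0.57	34.09	1.12
CP25	C. pilosula	Guanzhuang, Yaozhou, Tongchuan, Shaanxi, China	15	880	2016-11-15	P1	P1	39.65	0.17	34.66	0.83
CP26	C. pilosula	Hongtiguan, Pingshun, Changzhi, Shanxi, China	16	1245	2017-03-12	P4	P4	47.64	1.72	32.05	2.11
CP27	C. pilosula	Minyang, Minxian, Dingxi, Gansu, China		2305	2017-10-14	P1	P1	34.86	1.51	22.40	1.51
CP28	C. pilosula	Mazichuan, Minxian, Dingxi, Gansu, China	9	2510	2017-10-14	P1	P1	43.02	0.83	31.94	0.82
CP29	C. pilosula	Lichuan, Tanchang, Longnan, Gansu, China		2255	2017-10-14	P1	P1	40.71	1.63	25.37	1.88
CP30	C. pilosula	Pangjia, Tanchang, Longnan, Gansu, China		2431	2017-10-14	P1	P1	48.02	0.41	22.07	1.46
CP31	C. pilosula	Pangjia, Tanchang, Longnan, Gansu, China		2456	2017-10-14	P1	P1	43.49	0.46	20.11	1.74
CP32	C. pilosula	Awu, Tanchang, Longnan, Gansu, China		2351	2017-10-14	P1	P1	47.36	0.41	17.41	1.73
CP33	C. pilosula	Awu, Tanchang, Longnan, Gansu, China		2329	2017-10-14	P1	P1	28.92	0.49	29.00	5.90
CP34	C. pilosula	Hadapu, Tanchang, Longnan, Gansu, China		2445	2017-10-14	P5	P4	34.88	5.96
CP35	C. pilosula	Hadapu, Tanchang, Longnan, Gansu, China		2435	2017-10-14	P1	P1	46.22	6.07	28.87	1.41
CP36	C. pilosula	Hadapu, Tanchang, Longnan, Gansu, China		2188	2017-10-14	P1	P1	43.10	4.92	29.25	2.70
CP37	C. pilosula	Hadapu, Tanchang, Longnan, Gansu, China		2242	2017-10-14	P5	P3	39.67	6.60
CP38	C. pilosula	Pangjia, Tanchang, Longnan, Gansu, China		2320	2017-10-14	P4	P5	24.14	0.85	16.47	0.66
CP39	C. pilosula	Pangjia, Tanchang, Longnan, Gansu, China		2306	2017-10-14	P1	P1	34.67	1.01	42.17	0.71
CPM40	C. pilosula var. modesta	Danbao, Wenxian, Longnan, Gansu, China	17	895	2016-10-15	PM1	PM1	36.99	4.01	38.67	0.54
CPM41	C. pilosula var. modesta	Koutouba, Wenxian, Longnan, Gansu, China	18	1266	2016-10-15	PM1	PM1	39.29	0.25	33.92	1.33
CPM42	C. pilosula var. modesta	Shifang, Wenxian, Longnan, Gansu, China	19	995	2016-10-28	PM1	PM2	36.88	0.49	21.23	0.66
CPM43	C. pilosula var. modesta	Baoziba, Wenxian, Longnan, Gansu, China	20	1634	2016-10-28	PM1	PM2	22.94	0.80	19.67	0.95
CPM44	C. pilosula var. modesta	Baoziba, Wenxian, Longnan, Gansu, China		1480	2016-10-28	PM2	PM3			25.56	1.40
CPM45	C. pilosula var. modesta	Zhongzhai, Wenxian, Longnan, Gansu, China	21	1361	2016-10-28	PM3	PM2	27.35	1.01
CT46	C. tangshen	Banqiao, Enshi, Enshi, Hubei, China	22	1775	2016-08-18	T1	T1
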