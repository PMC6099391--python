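label	species_context	gc_percent	g122	g135	g226	g500	parents	n_specimens	accession
P0	C. pilosula	60.61	C	G	C	G			EF190460
P1	C. pilosula	60.31	Y:T>C	G	Y:C>T	G	P0xS0	33
P2	C. pilosula	60.46	C	G	Y:C>T	G		1
P3	C. pilosula	60.31	Y:T>C	G	Y:T>C	G	P0xS0	1
P4	C. pilosula	60.31	Y:C>T	G	Y:C>T	G	P0xS0	2
P5	C. pilosula	60.46	Y:C>T	G	C	G	P0xPM0	2
PM0	C. pilosula var. modesta	60.46	T	G	C	G			EF190461
PM1	C. pilosula var. modesta	60.31	Y:T>C	G	Y:C>T	G	P0xS0	4
PM2	C. pilosula var. modesta	60.31	T	G	Y:C>T	G	PM0xS0	1
PM3	C. pilosula var. modesta	60.46	Y:T>C	G	C	G	P0xPM0	1
T0	C. tangshen	60.31	T	G	C	A			EF190462
T1	C. tangshen	60.15	T	R	C	R		1
S0	unidentified	60.31	T	G	T	G			AB769272
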