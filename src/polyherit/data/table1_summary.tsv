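row	size_mb	Al	Br	CCN	Cr	Lr	Pn	Pt	SNG	SNL	Sr	YLS	Yr
He	16946	50.3	51.1	46.2	49.8	49.3	49.1	48.2	60.5	49.7	44.8	54.3	51.0
Group1	2252	13.8	19.8	10.1	18.7	9.2	3.3	12.3	16.3	22.5	3.2	12.0	6.8
Group2	2556	20.5	21.7	22.9	9.2	17.2	14.1	7.0	0.7	15.5	21.4	20.4	5.9
Group3	2592	21.5	14.5	20.2	29.9	14.5	19.4	25.4	25.0	14.1	15.5	19.7	21.1
Group4	2326	6.5	7.4	17.3	31.6	10.7	15.5	31.9	13.7	9.3	16.7	15.1	5.3
Group5	2447	7.0	11.1	13.4	1.1	10.2	18.2	15.0	21.7	12.3	11.3	12.6	29.3
Group6	2331	18.2	14.2	7.6	3.3	17.4	10.1	5.2	16.8	14.6	5.8	11.0	0
Group7	2442	12.5	11.4	8.5	6.1	20.6	19.4	3.1	5.7	11.7	26.2	9.4	31.5
A	5727	37.2	32.2	23.5	29.1	41.0	20.2	23.8	40.3	19.5	19.4	16.5	18.6
B	6274	21.5	34.1	34.6	25.7	27.6	48.9	29.8	25.8	44.5	66.8	39.9	31.8
D	4945	41.4	33.7	41.9	45.2	31.4	31.0	46.4	33.9	36.0	13.8	43.6	49.6
ChiP	NA	0.003	NA	0.01	0.002	NA	0.009	0.001	NA	0.01	0	0	0
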