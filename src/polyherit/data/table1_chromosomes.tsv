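chromosome	size_mb	Al	Br	CCN	Cr	Lr	Pn	Pt	SNG	SNL	Sr	YLS	Yr
1A	798	3.6	7.2	3.5	10.4	6.4	0	6.8	5.1	0	0	3.9	5.7
2A	899	0	7.3	3.8	0	7.4	0	0	0.2	5.5	0	2.4	0
3A	828	7.5	4.3	6.4	0	7.2	9.0	4.7	4.7	0.8	0	1.6	9.4
4A	856	5.0	7.0	9.8	12.6	7.4	7.6	6.0	7.7	0	1.3	7.5	0
5A	827	6.1	6.3	0	0	2.6	0.8	2.1	11.4	5.2	0	0.5	3.4
6A	705	8.6	0	0	0	4.9	0	1.0	5.5	7.9	5.8	0.5	0
7A	814	6.4	0	0	6.1	5.1	2.7	3.1	5.7	0	12.4	0	0
1B	849	0	0	0	0	0	0	0	0.7	14.5	3.2	4.2	1.1
2B	928	2.8	11.4	0	3.8	2.6	6.0	7.0	0.6	7.8	18.1	7.8	1.1
3B	993	7.2	8.3	11.7	6.4	7.3	6.8	13.8	10.9	5.8	14.0	8.3	4.0
4B	821	1.4	0.4	0	11.2	3.3	7.9	8.9	1.1	9.3	15.5	7.6	2.2
5B	870	0.9	0.7	6.8	1.0	5.3	11.1	0	3.4	7.0	6.8	12.1	15.7
6B	913	9.1	10.5	7.6	3.3	4.4	10.1	0	9.2	0	0	0	0
7B	900	0	3.0	8.5	0	4.6	7.1	0	0	0	9.3	0	7.7
1D	605	10.1	12.6	6.6	8.3	2.8	3.3	5.5	10.5	8.0	0	3.8	0
2D	729	17.6	3.1	19.1	5.3	7.2	8.1	0	0	2.2	3.3	10.1	4.7
3D	771	6.9	1.9	2.1	23.5	0	3.6	6.9	9.4	7.4	1.4	9.8	7.7
4D	649	0	0	7.6	7.8	0	0	17.0	4.9	0	0	0	3.2
5D	750	0	4.1	6.6	0.1	2.3	6.3	12.9	6.9	0	4.5	0	10.2
6D	713	0.5	3.7	0	0	8.1	0	4.2	2.1	6.7	0	10.5	0
7D	728	6.1	8.4	0	0	10.9	9.6	0	0	11.7	4.6	9.4	23.8
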