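stress	A	B	D	Groups	All
SNL	-0.329	-0.435	0.007	-0.273	-0.067
SNG	-0.240	0.668	-0.283	-0.084	-0.045
YLS	0.382	-0.024	0.438	0.690	0.054
Cr	0.121	-0.049	0.119	0.002	-0.118
Lr	0.426	0.628	0.176	0.438	0.139
Sr	-0.389	0.208	0.620	0.597	0.451
Yr	0.006	-0.093	0.474	0.413	-0.062
CCN	0.502	0.671	-0.110	0.674	0.067
Pn	0.270	0.126	0.428	0.700	0.336
Pt	0.032	0.463	-0.223	0.004	-0.134
Br	0.683	0.764	-0.463	0.189	0.182
Al	-0.742	0.654	-0.022	0.536	-0.204
Combined	0.0407	0.25	0.075	0.27	0.043
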