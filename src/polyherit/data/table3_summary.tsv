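row	Al	Br	CCN	Cr	Lr	Pn	Pt	SNG	SNL	Sr	YLS	Yr
He	0.503	0.511	0.462	0.498	0.493	0.491	0.482	0.605	0.497	0.448	0.543	0.510
A_contribution_pct	37.3	42.2	23.4	25.3	31.8	23.5	15.7	27.5	13.9	18.9	7.8	17.8
B_contribution_pct	22.9	28.0	29.9	30.7	27.7	47.5	18.6	19.8	37.7	58.3	40.8	27.9
D_contribution_pct	39.8	29.8	46.8	44.0	40.5	29.0	65.7	52.7	48.5	22.8	51.4	54.3
ChiP	0.008	NA	0.001	0.005	0.03	0.05	0	0	0	0	0	0
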