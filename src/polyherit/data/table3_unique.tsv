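chromosome	Al	Br	CCN	Cr	Lr	Pn	Pt	SNG	SNL	Sr	YLS	Yr
1A	0.013	0.004	0.007	0.027	0.013	0.001	0.013	0.013	-0.011	-0.014	-0.001	0.024
2A	0.012	0.007	0.009	0.009	0.018	0.007	-0.002	-0.002	0.007	-0.013	0.002	-0.005
3A	0.018	0.012	0.011	0.007	0.012	0.017	0.005	0.008	-0.002	0.002	0.001	0.035
4A	0.016	0.005	0.03	0.034	0.01	0.013	0.006	0.016	0.005	0	0.016	-0.002
5A	0.009	0.015	-0.002	-0.006	-0.003	0.001	0.003	0.02	0.007	-0.007	-0.001	0.008
6A	0.02	0.012	0.004	0.008	0.009	0.004	-0.005	0.012	0.012	0.015	-0.009	0
7A	0.016	0.037	0.011	0.008	0.008	0.009	0.006	0.006	0.001	0.022	0.006	0.005
1B	-0.016	0.009	-0.009	-0.01	0.005	0.01	-0.012	-0.007	0.026	-0.003	-0.001	0.005
2B	0.007	0.048	0.017	0.006	0.002	0.017	0.004	-0.002	0.017	0.04	0.026	0.002
3B	0.02	0.001	0.031	0.028	0.019	0.008	0.024	0.02	0.017	0.025	0.018	0.001
4B	-0.007	-0.003	-0.011	0.061	0.011	0.019	0.011	0	0.025	0.03	0.02	0.038
5B	0.001	-0.002	0.007	0.001	0.013	0.018	-0.005	0.014	0.001	0.008	0.037	0.042
6B	0.033	0.003	0.02	0.012	0.006	0.029	-0.002	0.02	0.001	-0.008	0.029	0.01
7B	0.003	-0.003	0.017	0.005	0.005	0.004	0	-0.021	-0.001	0.017	-0.012	0.015
1D	0.033	-0.009	0.008	0.028	-0.003	0.008	0.007	0.058	0.017	0.01	0.011	0.027
2D	0.04	0	0.098	0.015	0.021	0.017	0.017	0.024	0.003	0.004	0.015	0.024
3D	0.013	0.005	-0.005	0.097	0.013	0.007	0.011	0.013	0.023	0.006	0.032	0.024
4D	-0.001	0.017	0.017	0.017	0.004	0	0.053	0.016	0.006	-0.008	0.009	0.012
5D	0.013	0.017	0.008	0.001	0.004	0.011	0.036	0.016	0.014	0.017	0.04	0.055
6D	-0.004	0.007	0.008	0.004	0.023	-0.003	0.01	-0.002	0.02	0.005	0.029	0.013
7D	0.012	0.019	0.005	0	0.024	0.021	0.004	0.017	0.029	0.005	0.028	0.065
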