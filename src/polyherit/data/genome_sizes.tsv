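chromosome	size_mb
1A	798
2A	899
3A	828
4A	856
5A	827
6A	705
7A	814
1B	849
2B	928
3B	993
4B	821
5B	870
6B	913
7B	900
1D	605
2D	729
3D	771
4D	649
5D	750
6D	713
7D	728
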