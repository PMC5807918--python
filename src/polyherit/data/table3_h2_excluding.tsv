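chromosome	Al	Br	CCN	Cr	Lr	Pn	Pt	SNG	SNL	Sr	YLS	Yr
1A	0.49	0.507	0.455	0.472	0.48	0.49	0.469	0.592	0.508	0.462	0.544	0.486
2A	0.491	0.504	0.453	0.489	0.475	0.485	0.484	0.607	0.49	0.461	0.541	0.515
3A	0.486	0.499	0.451	0.491	0.481	0.474	0.477	0.597	0.499	0.446	0.543	0.475
4A	0.487	0.506	0.432	0.465	0.484	0.478	0.476	0.589	0.492	0.448	0.528	0.512
5A	0.494	0.496	0.464	0.504	0.496	0.49	0.479	0.586	0.49	0.455	0.545	0.502
6A	0.483	0.499	0.458	0.49	0.484	0.487	0.487	0.593	0.485	0.433	0.552	0.51
7A	0.487	0.474	0.451	0.49	0.485	0.482	0.476	0.599	0.496	0.426	0.537	0.505
1B	0.519	0.502	0.471	0.508	0.489	0.481	0.494	0.612	0.471	0.451	0.544	0.505
2B	0.496	0.463	0.445	0.492	0.491	0.474	0.478	0.607	0.48	0.408	0.517	0.508
3B	0.483	0.51	0.431	0.47	0.474	0.483	0.458	0.585	0.48	0.423	0.526	0.509
4B	0.51	0.514	0.473	0.437	0.482	0.472	0.471	0.605	0.473	0.418	0.523	0.472
5B	0.502	0.513	0.455	0.497	0.48	0.473	0.487	0.591	0.496	0.44	0.506	0.469
6B	0.471	0.508	0.443	0.486	0.487	0.462	0.484	0.585	0.496	0.456	0.514	0.5
7B	0.5	0.514	0.445	0.493	0.488	0.487	0.482	0.626	0.498	0.431	0.555	0.496
1D	0.47	0.52	0.454	0.47	0.496	0.483	0.475	0.547	0.48	0.438	0.532	0.484
2D	0.463	0.511	0.364	0.483	0.472	0.475	0.465	0.581	0.494	0.444	0.528	0.486
3D	0.49	0.506	0.467	0.401	0.48	0.484	0.471	0.592	0.474	0.442	0.511	0.486
4D	0.504	0.494	0.445	0.481	0.489	0.491	0.429	0.589	0.491	0.456	0.534	0.498
5D	0.49	0.494	0.454	0.497	0.489	0.481	0.446	0.589	0.483	0.431	0.503	0.455
6D	0.507	0.504	0.454	0.494	0.47	0.494	0.473	0.607	0.477	0.443	0.514	0.497
7D	0.491	0.493	0.457	0.498	0.469	0.47	0.478	0.589	0.469	0.443	0.515	0.445
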