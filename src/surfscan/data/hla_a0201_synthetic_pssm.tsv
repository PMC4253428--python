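position	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
1	7.328	0.910	1.350	6.055	9.904	3.072	6.429	7.870	8.387	0.089	7.010	7.937	3.325	8.442	3.998	7.822	1.386	0.504	5.488	8.060
2	2.157	5.070	0.565	4.634	3.144	9.318	4.088	2.338	4.267	11.691	11.309	1.316	6.654	1.919	7.623	3.479	8.088	4.255	8.833	8.737
3	2.692	3.086	5.386	5.407	6.862	0.313	4.773	4.866	9.343	7.062	3.264	4.459	7.933	3.140	2.460	5.230	6.690	2.699	9.223	9.719
4	3.783	0.420	7.917	6.555	5.183	0.387	6.801	0.079	9.867	6.898	7.424	5.407	5.736	6.330	2.300	3.120	3.746	7.507	5.501	6.117
5	3.062	8.036	0.717	3.321	4.618	2.140	1.097	7.770	7.773	1.261	3.910	5.307	5.131	7.466	7.191	6.001	2.017	2.578	7.169	2.908
6	0.300	5.877	6.990	6.061	4.642	8.243	6.855	9.502	8.767	5.186	6.049	7.191	4.983	1.742	0.999	2.349	7.849	0.651	4.177	1.073
7	5.237	5.242	3.089	0.941	9.128	9.812	3.323	2.406	1.516	3.446	8.988	7.332	2.336	4.428	6.341	3.351	6.641	9.522	5.217	8.068
8	5.953	9.981	9.306	1.110	3.676	4.199	3.943	7.105	5.896	3.786	5.251	8.094	9.373	6.559	4.281	2.407	5.542	0.019	4.970	9.735
9	4.993	7.944	1.042	4.382	2.279	2.891	3.428	12.309	0.405	11.580	3.497	4.974	5.733	4.836	8.335	0.369	8.933	11.689	5.447	3.701
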