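prefix	third_pair	amino_acid	usage_cg	dpref_ta_to_cg	s_cg	n_cg	s_ta	n_ta	mean_d_cg_to_ta	mean_d_ta_to_cg
GC	C/T	Ala	0.757	0.972	684	24976	193	8275	2.251	3.539
GG	C/T	Gly	0.747	0.652	574	19504	226	7027	2.336	3.319
CC	C/T	Pro	0.774	0.829	428	14444	97	4144	2.185	3.557
AC	C/T	Thr	0.724	0.792	458	15326	104	6117	2.216	3.808
GT	C/T	Val	0.663	0.737	355	12959	98	7011	2.352	3.622
CG	C/T	Arg4	0.692	0.591	509	14398	194	7044	2.369	3.170
CT	C/T	Leu4	0.728	0.774	525	14629	116	5869	2.051	3.776
TC	C/T	Ser4	0.743	0.638	436	14149	150	5164	1.959	4.093
AT	C/T	Ile	0.601	0.929	753	21090	241	15310	2.112	3.560
AG	C/T	Ser2	0.708	0.567	468	16090	223	7353	2.348	3.090
AA	C/T	Asn	0.552	0.922	728	21727	553	19956	2.404	3.562
GA	C/T	Asp	0.505	0.784	684	21184	618	24206	2.367	3.565
TG	C/T	Cys	0.723	0.608	338	10916	162	4458	2.346	3.525
CA	C/T	His	0.578	0.662	338	11373	255	9781	1.976	3.333
TT	C/T	Phe	0.629	1.064	984	20878	372	13361	2.181	4.024
TA	C/T	Tyr	0.621	0.842	511	15979	338	11392	2.160	3.781
GC	G/A	Ala	0.522	0.567	278	8438	161	8691	2.392	3.503
GG	G/A	Gly	0.361	0.208	229	4821	201	9551	2.655	2.960
CC	G/A	Pro	0.557	0.653	308	8910	181	8456	2.360	3.508
AC	G/A	Thr	0.571	0.620	408	12025	181	10085	2.368	3.320
GT	G/A	Val	0.849	0.942	631	23036	113	4307	2.019	3.894
CG	G/A	Arg4	0.566	0.442	217	5828	115	5398	2.618	3.104
CT	G/A	Leu4	0.874	1.140	959	34643	169	5649	2.088	4.172
TC	G/A	Ser4	0.730	0.684	399	12539	102	5237	2.120	3.941
AG	G/A	Arg2	0.574	0.283	145	4236	70	3394	2.159	3.171
TT	G/A	Leu2	0.827	0.138	334	12658	74	2788	2.135	3.824
GA	G/A	Glu	0.722	1.448	1323	38468	408	16383	2.225	3.733
CA	G/A	Gln	0.753	1.312	802	28876	232	10386	2.170	3.608
AA	G/A	Lys	0.723	1.400	1165	37359	335	14953	2.039	3.878
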