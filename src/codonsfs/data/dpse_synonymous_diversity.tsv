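class	n_syn	s_syn	s_syn_biallelic	d_syn	theta_w_per_bp	d_per_bp
All	543985.0	35376	33729	41360	0.022203	0.076032
ala	50380.0	2661	2513	3126	0.018033	0.062048
arg	48644.0	2558	2365	3047	0.017954	0.062639
asn	13894.3	1282	1281	1621	0.031502	0.116667
asp	15130.0	1303	1302	1835	0.029403	0.121282
cys	5124.6	500	500	576	0.033311	0.112398
glu	18283.6	1733	1731	1936	0.032361	0.105887
gln	12420.7	1034	1034	1151	0.028422	0.092668
gly	40903.0	2600	2427	2932	0.021702	0.071682
his	7051.3	593	593	813	0.028713	0.115298
ile	31135.4	1833	1782	2028	0.020100	0.065135
leu	91350.6	5619	5139	6313	0.021001	0.069107
lys	17437.3	1500	1500	1817	0.029370	0.104202
phe	11413.0	1358	1356	1634	0.040624	0.143170
pro	35924.0	2137	1975	2481	0.020310	0.069062
ser	44903.3	2865	2735	3331	0.021784	0.074182
thr	43553.0	2406	2257	2775	0.018861	0.063715
tyr	9123.6	851	849	1062	0.031845	0.116401
val	47313.0	2543	2390	2882	0.018351	0.060913
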