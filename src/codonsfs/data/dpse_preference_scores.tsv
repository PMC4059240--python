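codon	amino_acid	score
GCC	ala	0.571
GCG	ala	0.076
GCT	ala	-0.401
GCA	ala	-0.491
CGC	arg	0.501
CGG	arg	0.163
CGT	arg	-0.090
AGG	arg	-0.188
CGA	arg	-0.279
AGA	arg	-0.471
AAC	asn	0.461
AAT	asn	-0.461
GAC	asp	0.392
GAT	asp	-0.392
TGC	cys	0.304
TGT	cys	-0.304
CAG	gln	0.656
CAA	gln	-0.656
GAG	glu	0.724
GAA	glu	-0.724
GGC	gly	0.430
GGG	gly	-0.083
GGT	gly	-0.222
GGA	gly	-0.291
CAC	his	0.331
CAT	his	-0.331
ATC	ile	0.584
ATT	ile	-0.345
ATA	ile	-0.405
CTG	leu	0.697
CTC	leu	0.316
TTG	leu	-0.434
CTA	leu	-0.443
CTT	leu	-0.458
TTA	leu	-0.572
AAG	lys	0.700
AAA	lys	-0.700
TTC	phe	0.534
TTT	phe	-0.534
CCC	pro	0.425
CCG	pro	0.211
CCT	pro	-0.404
CCA	pro	-0.442
TCC	ser	0.287
AGC	ser	0.270
TCG	ser	0.228
AGT	ser	-0.297
TCT	ser	-0.351
TCA	ser	-0.456
ACC	thr	0.435
ACG	thr	0.204
ACT	thr	-0.357
ACA	thr	-0.416
TAC	tyr	0.421
TAT	tyr	-0.421
GTG	val	0.453
GTC	val	0.245
GTA	val	-0.489
GTT	val	-0.492
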