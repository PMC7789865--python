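amino_acid	codon	n_high	n_low	reconstructed
Phe	TTT	1118	265	0
Phe	TTC	567	986	0
Leu	TTA	631	110	0
Leu	TTG	861	388	0
Leu	CTT	884	294	0
Leu	CTC	257	1132	0
Leu	CTA	325	162	0
Leu	CTG	365	564	0
Ile	ATT	1010	301	0
Ile	ATC	444	790	0
Ile	ATA	542	199	0
Met	ATG	967	676	0
Val	GTT	1045	337	0
Val	GTC	304	735	0
Val	GTA	463	146	0
Val	GTG	579	858	0
Ser	TCT	1103	338	0
Ser	TCC	349	873	0
Ser	TCA	976	225	0
Ser	TCG	146	500	0
Ser	AGT	669	166	0
Ser	AGC	373	548	0
Pro	CCT	829	339	0
Pro	CCC	167	619	0
Pro	CCA	666	228	0
Pro	CCG	62	660	0
Thr	ACT	846	247	0
Thr	ACC	252	731	0
Thr	ACA	752	195	0
Thr	ACG	90	432	0
Ala	GCT	1023	491	0
Ala	GCC	250	1260	0
Ala	GCA	1005	318	0
Ala	GCG	83	738	0
Tyr	TAT	779	126	0
Tyr	TAC	365	689	0
His	CAT	750	169	0
His	CAC	249	540	0
Gln	CAA	846	287	0
Gln	CAG	626	619	0
Asn	AAT	1231	260	0
Asn	AAC	562	787	0
Lys	AAA	1149	290	0
Lys	AAG	1193	956	0
Asp	GAT	1708	489	0
Asp	GAC	539	908	1
Cys	TGT	621	146	0
Cys	TGC	229	449	0
Trp	TGG	412	383	0
Arg	CGT	244	115	0
Arg	CGC	71	407	0
Arg	CGA	124	167	0
Arg	CGG	67	347	0
Arg	AGA	852	191	0
Arg	AGG	529	452	0
Gly	GGT	724	338	0
Gly	GGC	501	737	1
Gly	GGA	501	738	1
Gly	GGG	502	738	1
TER	TAA	49	48	0
TER	TAG	30	30	0
TER	TGA	53	54	0
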