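# gene_id=LOC132609965	chromosome=9	table=chr9
positions	ref_codon	alt_codons	aa_printed	ref_token	Lb1	Lb2	Lb3	Lb4	Lb5	Lb6w	Lb7w	Lb8w
473	CCT	CCC	Pro/Pro (silent)	Pro	Pro	Pro	Pro	Pro	Pro	h75	h56	Pro
479	TAC	TAT	Tyr/Tyr (silent)	Tyr (TAC)	Tyr(TAT)	Tyr(TAT)	Tyr(TAT)	Tyr(TAT)	Tyr(TAT)	h50	h44	h33
498	GCC	ACC	Ala/Thr	Ala	h61	h41	h67	h67	h17	h40	h50	Ala
548	TGT	TGC	Cys/Cys (silent)	Cys (TGT)	Cys (TGT)	Cys (TGT)	Cys (TGT)	Cys (TGT)	Cys (TGT)	h50	h54	Cys (TGT)
555-557	TCT	GCT,TCA,TCG	Ser/Ala/Ser/Ser	Ser	Ala	Ala	Ala	Ala	Ala	h50	h46	h33
563	TCT	TCC	Ser/Ser (silent)	Ser (TCT)	Ser(TCC)	Ser(TCC)	Ser(TCC)	Ser(TCC)	Ser(TCC)	h67	h46	Ser(TCT)
625	GCG	GTG	Ala/Val	Ala	Val	Val	Val	Val	Val	Ala	h70	h40
627	GCT	TCT	Ala/Ser	Ala	Ser	Ser	Ser	Ser	Ser	Ser	Ser	h40
643	TTC	TCC	Phe/Ser	Phe	Ser	Ser	Ser	Ser	Ser	Ser	Ser	Ser
668	CTT	CTC	Leu/Leu (silent)	Leu (CTT)	Leu(CTC)	Leu(CTC)	Leu(CTC)	Leu(CTC)	Leu(CTC)	h33	h60	h50
713	TCG	TCC	Ser/Ser (silent)	Ser (TCG)	Ser(TCC)	Ser(TCC)	Ser(TCC)	Ser(TCC)	Ser(TCC)	h25	h33	h75
977	TCG	TCA	Ser/Ser (silent)	Ser (TCG)	Ser (TCA)	Ser (TCA)	Ser (TCA)	Ser (TCA)	Ser (TCA)	h33	h20	h60
982	TAT	TGT	Tyr/Ser	Tyr	h50	h67	h50	h50	h50	Tyr	Tyr	Tyr
986	CGG	CGA	Arg/Arg (silent)	Arg (CGG)	Arg (CGA)	Arg (CGA)	Arg (CGA)	Arg (CGA)	Arg (CGA)	h33	h20	h63
1076	GAG	GAA	Glu/Glu (silent)	Glu(GAG)	Glu (GAA)	Glu (GAA)	Glu (GAA)	Glu (GAA)	Glu (GAA)	h33	h20	h70
1079	AAA	AAG	Lys/Lys (silent)	Lys (AAA)	h58	h47	h40	h43	h67	h25	h25	h70
1223	CCA	CCC	Pro/Pro (silent)	Pro (CCA)	h50	h48	h22	h60	h57	Pro (CCA)	Pro (CCA)	Pro (CCA)
1256	AGG	AGA	Arg/Arg (silent)	Arg (AGG)	h41	h56	h71	h56	h50	h37	h67	Arg(AGA)
1285	GTG	GCG	Val/Ala	Val	h42	h44	h67	h60	h62	h37	h775	Ala
1304	TCG	TCT	Ser/Ser (silent)	Ser(TCG)	h65	h48	h17	h50	h33	Ser (TCG)	Ser (TCG)	Ser (TCG)
1394	CTG	CTC	Leu/Leu (silent)	Leu(CTG)	Leu(CTC)	Leu(CTC)	Leu(CTC)	Leu(CTC)	Leu(CTC)	h50	h50	Leu(CTC)
1421	TTA	TTG	Leu/Leu (silent)	Leu (TTA)	h67	h62	h60	Leu (TTG)	Leu (TTA)	Leu (TTA)	Leu (TTA)	Leu (TTA)
1466	ACT	ACA	Thr/Thr (silent)	Thr(ACT)	Thr (ACA)	Thr (ACA)	Thr (ACA)	Thr (ACA)	Thr (ACA)	h50	h40	h57
1550	ACA	ACG	Thr/Thr (silent)	Thr(ACA)	Thr (ACG)	Thr (ACG)	Thr (ACG)	Thr (ACG)	Thr (ACG)	h33	h50	h57
1580	ATC	ATA	Ile/Ile (silent)	Ile (ATC)	Ile (ATA)	Ile (ATA)	Ile (ATA)	Ile (ATA)	Ile (ATA)	h33	h57	h71
1671-1672	GGA	AGA,GAA	Gly/Arg/Glu	Gly	h16	h9	h16	h11	h6	Gly	Gly	Gly
1689	GCT	TCT	Ala/Ser	Ala	h23	h15	h21	h20	h24	Ala	Ala	Ala
1726	ACA	AAA	Thr/Lys	Thr	h10	h17	h33	h18	h23	h57	h17	h67
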