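# gene_id=LOC132634709	chromosome=4	table=chr4
positions	ref_codon	alt_codons	aa_printed	ref_token	Lb1	Lb2	Lb3	Lb4	Lb5	Lb6w	Lb7w	Lb8w
517	AAT	AGT	Asn/Ser	Asn	h69	h59	h67	h50	h75	Asn	Asn	Asn
529	AGC	ATC	Ser/Ile	Ser	h69	h57	h40	h50	h75	Ser	Ser	Ser
537	TTA	CTA	Leu/Leu (silent)	Leu (TTA)	Leu (CTA)	Leu (CTA)	Leu (CTA)	Leu (CTA)	Leu (CTA)	h33	h20	h30
590	CTT	CTC	Leu/Leu (silent)	Leu (CTT)	Leu (CTC)	Leu (CTC)	Leu (CTC)	Leu (CTC)	Leu (CTC)	h37	Leu (CTT)	h40
746	TGC	TGT	Cys/Cys (silent)	Cys (TGC)	Cys (TGT)	Cys (TGT)	Cys (TGT)	Cys (TGT)	Cys (TGT)	h50	h17	h30
749	CTG	CTC	Leu/Leu (silent)	Leu (CTG)	h35	h40	h50	h33	h20	h43	h29	h36
767	CTA	CTG	Leu/Leu (silent)	Leu (CTA)	Leu (CTG)	Leu (CTG)	Leu (CTG)	Leu (CTG)	Leu (CTG)	h50	h37	h30
804	CCA	ACA	Pro/Thr	Pro	h78	h45	h25	h80	h60	Pro	Pro	Pro
873	GCT	TCT	Ala/Ser	Ala	h67	h56	h18	h60	h80	Ala	Ala	Ala
956	ATG	ATT	Met/Ile	Met	h42	h35	h37	h40	h80	Met	Met	Met
1190	TCA	TCT	Ser/Ser (silent)	Ser (TCA)	h46	h92	h50	h45	h60	Ser (TCA)	Ser (TCA)	Ser (TCA)
1208	GCA	GCC	Ala/Ala (silent)	Ala (GCA)	h50	h7	h50	h60	h40	h75	h40	h33
1247	AGT	AGC	Ser/Ser (silent)	Ser (AGT)	h50	h20	h57	h70	h25	h80	h45	h40
1312	AAA	AGA	Lys/Arg	Lys	Arg	Arg	Arg	Arg	Arg	h80	h40	h50
1352	TGC	TGT	Cys/Cys (silent)	Cys(TGC)	h42	h39	h53	h57	h44	Cys (TGC)	Cys (TGC)	h14
1439	AAA	AAG	Lys/Lys (silent)	Gly	h59	h65	h60	h18	h60	h67	h57	h57
1457	CAG	CAA	Gln/Gln (silent)	Gln (CAG)	Gln (CAG)	Gln (CAG)	Gln (CAG)	Gln (CAG)	Gln (CAG)	h67	h57	h57
1520	ATG	ATT	Met/Ile	Met	h43	h54	h67	h83	h45	Met	Met	Met
1631	TAC	TAT	Tyr/Tyr (silent)	Tyr (TAC)	Tyr (TAT)	Tyr (TAT)	Tyr (TAT)	Tyr (TAT)	Tyr (TAT)	h75	h25	h73
1715	ATA	ATT	Ile/Ile (silent)	Ile	h61	h47	h50	h50	h50	h67	h33	h60
1761	ACG	TCG	Thr/Ser	Tyr	h67	h71	h50	h37	h33	Tyr	Tyr	Tyr
1886	GGC	GGG	Gly/Gly (silent)	Gly (GGC)	Gly (GGC)	h36	h54	h86	h30	h83	h43	h75
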