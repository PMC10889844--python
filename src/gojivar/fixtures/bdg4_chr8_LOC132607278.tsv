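# gene_id=LOC132607278	chromosome=8	table=chr8
positions	ref_codon	alt_codons	aa_printed	ref_token	Lb1	Lb2	Lb3	Lb4	Lb5	Lb6w	Lb7w	Lb8w
129	TGG	TTG	Trp/Leu	Trp	h50	h67	h67	h57	h50	h33	h75	h75
146	AAA	GAA	Lys/Glu	Lys	Glu	Glu	Glu	Glu	Glu	Glu	Glu	Glu
174	GTA	GCA	Val/Ala	Val	h45	h58	h17	h33	h71	Val	Val	Val
202	GAG	GAC	Glu/Asp	Glu	Asp	h93	Asp	Asp	Asp	h41	h62	Asp
209	TTT	CTT	Phe/Leu	Phe	Phe	Phe	Phe	Phe	Phe	h46	h62	h67
287-288	AAA	CGA	Lys/Arg	Lys	h50	h47	h20	h50	h82	Lys	h14/Lys	Lys
392-394	AAA	GAC	Lys/Asp	Lys	h35	h53	h33	h33	h67	Lys	Lys	Lys
617	GAA	AAA	Glu/Lys	Glu	Glu	Glu	Glu	Glu	Glu	h57	h75	h75
648	GCA	GGA	Ala/Gly	Ala	Ala	Ala	Ala	Ala	Ala	h57	h12	h14
688	AAC	AAT	Asn/Asn (sIlent)	Asn	h41	h36	h57	h50	h25	Asn	Asn	Asn
694	TGC	TGT	Cys/Cys (sIlent)	Cys	h41	h36	h57	h43	h14	Cys	Cys	Cys
799	GTA	GTG	Val/Val (sIlent)	Val(GTA)	Val(GTA)	Val(GTA)	Val(GTA)	Val(GTA)	Val(GTA)	h50	h40	Val(GTG)
824	TCT	CCT	Ser/Pro	Pro	Pro	Pro	Pro	Pro	Pro	h43	h45	Pro
864	TAC	TTC	Tyr/Phe	Tyr	Tyr	Tyr	Tyr	Tyr	Tyr	h50	h33	Tyr
891	AGT	ATT	Ser/Ile	Ser	h53	h58	h56	h78	h67	Ser	Ser	Ser
1023	TGG	TTG	Trp/Leu	Trp	h6	Trp	Trp	Trp	Trp	h50	h71	h43
1030	GGA	GGT	Gly/Gly (sIlent)	Gly (GGA)	h58	h22	h43	h56	h33	Gly (GGA)	Gly (GGA)	Gly (GGA)
1049	TGG	GGG	Trp/Gly	Trp	h38	h78	h43	h44	h71	Trp	Trp	Trp
1076	ATT	GTT	Ile/Val	Ile	Ile	Ile	Ile	Ile	Ile	h40	h50	h67
1150	TTT	TTA	Phe/Leu	Phe	Phe	Phe	Phe	Phe	Phe	h29	h50	h50
1151	ATG	GTG	Met/Val	Met	Met	Met	Met	Met	Met	h29	h50	h50
1266	CCT	CTT	Pro/Leu	Pro	h64	h75	h60	h64	h50	Pro	Pro	Pro
1270	GAA	GAT	Glu/Asp	Glu	Asp	Asp	Asp	Asp	Asp	h60	h62	Asp
1274	GAG	AAG	Glu/Lys	Glu	Glu	Glu	Glu	Glu	Glu	h60	h57	Lys
1304	ACT	TCT	Thr/Ser	Thr	h64	h73	h71	h86	h40	Thr	Thr	Thr
1338	TGT	TCT	Cys/Ser	Cys	h36	h23	h37	Ser	h71	Cys	Cys	Cys
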