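# Auditable corrections applied when loading the printed coding-SNP tables.
# The fixture TSVs preserve every cell exactly as published; each entry below
# replaces one printed token at load time, with the reason recorded here.
table	positions	column	printed	corrected	note
chr4	1439	ref_token	Gly	Lys	codons AAA/AAG encode Lys, not Gly
chr4	1761	ref_token	Tyr	Thr	reference codon ACG encodes Thr
chr4	1761	Lb6w	Tyr	Thr	follows the reference-token correction
chr4	1761	Lb7w	Tyr	Thr	follows the reference-token correction
chr4	1761	Lb8w	Tyr	Thr	follows the reference-token correction
chr8	824	ref_token	Pro	Ser	reference codon TCT encodes Ser; Pro is the alternate
chr9	982	aa_printed	Tyr/Ser	Tyr/Cys	alternate codon TGT encodes Cys, not Ser
chr9	1285	Lb7w	h775	h75	alternate-read percentage above 100 is impossible
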