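clone	total_bp	gene_count	gene_bp	gene_labels	repeat_count	repeat_bp
113H10	96426	1	885	ac	61	23570
99M22	102758	1	885	ac	78	28879
97L04	111044	1	963	sc	38	38432
62B24	90178	1	963	sc	44	28013
16B10	135393	1	786	l'sc	66	27144
104L14	115595	0	0	.	68	19608
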