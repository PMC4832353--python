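clone_a	pos_a	clone_b	pos_b
97L04	90093	62B24	14103
97L04	99269	62B24	21655
97L04	104855	62B24	27740
62B24	72470	16B10	2419
62B24	89286	16B10	19235
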