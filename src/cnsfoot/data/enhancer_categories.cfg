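# enhancer label -> category
sc-SOPE	wing_disc
L3/TSM	wing_disc
pTG	wing_disc
tr1-tr2	wing_disc
DCE	wing_disc
sc-UTR	UTR
l'sc-UTR	UTR
A	embryonic_ns
C	embryonic_ns
D	embryonic_ns
E	embryonic_ns
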