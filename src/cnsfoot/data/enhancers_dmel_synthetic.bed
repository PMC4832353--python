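track name=dmel_enhancers_synthetic
dmel	23322	23352	A	0	.
dmel	25809	25845	A	0	.
dmel	40104	40129	sc-SOPE	0	.
dmel	42355	42403	L3/TSM	0	.
dmel	42857	42923	sc-UTR	0	.
dmel	51056	51103	pTG	0	.
dmel	51963	52013	pTG	0	.
dmel	52754	52844	pTG	0	.
dmel	53730	53762	pTG	0	.
dmel	57554	57671	l'sc-UTR	0	.
dmel	66738	66764	C	0	.
dmel	68212	68243	C	0	.
dmel	68285	68311	C	0	.
dmel	69399	69423	C	0	.
dmel	69637	69686	C	0	.
dmel	72900	72925	tr1-tr2	0	.
dmel	90691	90719	D	0	.
dmel	109967	109997	E	0	.
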