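gene_a	gene_b	coefficient
CD1C	MUC5AC	-0.036
CD1D	DKK1	-0.209
ICAM1	MET	-0.023
ERAP2	SSTR1	0.739
CXCL9	APLNR	0.365
CXCL11	CD79A	0.119
CXCL11	PIK3R5	0.135
CXCL11	PRKCB	0.165
CXCL11	ZAP70	0.341
PLAU	ZYX	0.018
IRF3	MET	-0.454
IL1A	CCL23	0.015
OAS1	AGT	0.260
AGER	IL20RB	-0.300
PPARG	FGR	0.442
CHGA	IL22RA1	-0.571
EREG	RARB	0.260
GMFB	TGFA	-0.173
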