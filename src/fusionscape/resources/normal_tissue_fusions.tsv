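gene_a	gene_b
TFG	GPR128
SLC45A3	ELK4
CTBS	GNG5
AZGP1	GJC3
KANSL1	ARL17A
KANSL1	ARL17B
TTTY15	USP9Y
CHFR	GOLGA3
HARS2	ZMAT2
RRM2	C2orf48
NAIP	OCLN
PRIM1	NACA
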