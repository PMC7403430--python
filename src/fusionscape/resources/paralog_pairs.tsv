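gene_a	gene_b
HSPA1A	HSPA1B
DDX19A	DDX19B
CBWD1	CBWD2
SMN1	SMN2
GTF2H2	GTF2H2C
HIST1H2BC	HIST1H2BE
NBPF10	NBPF14
CYP2D6	CYP2D7
UGT1A1	UGT1A4
FAM72A	FAM72B
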