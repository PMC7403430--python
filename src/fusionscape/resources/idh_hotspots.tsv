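gene	codon	chrom	pos	ref	alt
IDH1	R132	2	209113112	C	T
IDH2	R172	15	90631934	C	T
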