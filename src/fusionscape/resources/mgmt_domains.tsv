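gene	domain	aa_start	aa_end
MGMT	dna_binding	92	135
MGMT	methyltransferase	136	176
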