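gene_a	gene_b	status
DCN	DLK1	present
DCN	MEG3	present
DLK1	MEST	present
IGF2	MEST	present
IGF2	RPL32	present
MEG3	MEST	present
DCN	IGF2	absent
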