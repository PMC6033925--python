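gene_a	gene_b	status
DLK1	MYH3	present
IGF2	MYH3	present
MEG3	MYH3	present
MEST	MYH3	present
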