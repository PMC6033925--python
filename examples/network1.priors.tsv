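gene_a	gene_b	status
DLK1	IGF2	present
DLK1	MEG3	present
IGF2	MEG3	present
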