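# Targeted-identification outcomes for the 15 query-fluid proteins absent
# from both reference databases: accession <TAB> peptide count or ND.
IPI00178854	1
IPI00332887	4
IPI00218803	7
IPI00855821	4
IPI00018276	ND
IPI00216250	1
IPI00479708	ND
IPI00022418	12
IPI00645363	7
IPI00470716	ND
IPI00003813	ND
IPI00435020	6
IPI00384998	4
IPI00451624	3
IPI00219664	1
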