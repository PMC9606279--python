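snp_id	chrom	pos	ref_allele	alt_allele	linked_disease	window_bp
rs886041026	chr16	67313415	C	T	SCA31	40000
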