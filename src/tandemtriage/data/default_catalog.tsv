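locus_id	gene	disease	chrom	start	end	pathogenic_motifs	benign_motifs	interruption_motifs	ref_units	normal_max_units	pathogenic_min_units	inheritance	motif_len
NOTCH2NLC	NOTCH2NLC	NIID	chr1	149390802	149390841	GGC		GGA	13	39	60	AD	3
ATXN8OS	ATXN8OS/ATXN8	SCA8	chr13	70139383	70139428	CTG	CTA	CCG	15	40	71	AD	3
ATXN3	ATXN3	SCA3	chr14	92071010	92071040	CAG			10	44	60	AD	3
TNRC6A	TNRC6A	BAFME6	chr16	24613438	24613528	TTTCA	TTTTA		18			AD	5
BEAN1	BEAN1	SCA31	chr16	66490396	66490461	TGGAA	TAAAA,TAGAA		13	5	110	AD	5
CACNA1A	CACNA1A	SCA6	chr19	13207858	13207897	CAG			13	18	20	AD	3
DMPK	DMPK	MyD	chr19	45770204	45770264	CTG		CCG,CGG,CTC	20	34	50	AD	3
NOP56	NOP56	SCA36	chr20	2652732	2652756	GGCCTG			4	14	650	AD	6
CSTB	CSTB	ULD	chr21	43776442	43776478	CCCCGCCCCGCG			3	3	30	AR	12
HTT	HTT	HD	chr4	3074876	3074939	CAG		CAACAG,CCG	21	26	36	AD	3
RFC1	RFC1	CANVAS	chr4	39348424	39348479	AAGGG,ACAGG	AAAAG,AAGAG		11	20	400	AR	5
PHOX2B	PHOX2B	CCHS	chr4	41745971	41746031	GCA,GCC,GCG,GCT			20	20	25	AD	3
SAMD12	SAMD12	BAFME1	chr8	118366812	118366912	TTTCA	TTTTA		20	2	20	AD	5
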