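chr5	112043194	112181936	APC
chr12	46123447	46301823	ARID2
chr17	37844166	37886679	ERBB2
chr12	25358179	25403854	KRAS
chr19	11071597	11176071	SMARCA4
chr17	7571719	7590868	TP53
chr11	108093210	108239829	ATM
chr4	153242409	153456185	FBXW7
chr3	52579367	52719933	PBRM1
chr8	128748314	128753680	MYC
chr2	148602085	148688393	ACVR2A
chr3	30647993	30735633	TGFBR2
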