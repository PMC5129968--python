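case	gene	protein_change	consequence	regions
MSS1	APC	p.E1554fs	frameshift_indel	T1;T2;T3
MSS1	ARID2	p.K15fs	frameshift_indel	T1;T2
MSS1	SMARCA4	p.R1157W	missense	T1
MSS1	SMARCA4	p.T910M	missense	T2
MSS1	ERBB2	p.V842I	missense	T1;T2
MSS2	APC	p.S1110fs	frameshift_indel	T1;T2;T3
MSS2	APC	p.R1450X	nonsense	T1;T2;T3
MSS2	ARID2	p.Q995X	nonsense	T1
MSS2	ARID2	p.E376X	nonsense	T2
MSS2	PBRM1	p.R710X	nonsense	T1;T2
MSS2	KRAS	p.G13D	missense	T3
MSS2	FBXW7	p.R367X	nonsense	T1
MSS2	FBXW7	p.R465C	missense	T2
MSS3	APC	p.E1554fs	frameshift_indel	T1;T2;T3
MSS3	APC	p.Q480X	nonsense	T1
MSS3	ARID2	p.Q480X	nonsense	T1
MSS3	ARID2	splice_site	splicing	T2
MSS3	TP53	p.R273C	missense	T1;T2
MSS3	ATM	p.R2443Q	missense	T3
MSI-H1	APC	p.R215X	nonsense	T1;T2;T3
MSI-H1	APC	p.K1452fs	frameshift_indel	T1;T2;T3
MSI-H1	BRD4	p.P1074fs	frameshift_indel	T1
MSI-H1	KMT2D	p.S2337fs	frameshift_indel	T2
MSI-H1	BCL9	p.M1400fs	frameshift_indel	T1;T2;T3
MSI-H1	CASP8	p.K229fs	frameshift_indel	T1;T2;T3
MSI-H1	IL21R	p.T465fs	frameshift_indel	T1;T2;T3
MSI-H1	MAP3K1	p.N325fs	frameshift_indel	T1;T2;T3
MSI-H1	UBR5	p.E2121fs	frameshift_indel	T1;T2;T3
MSI-H1	ACVR2A	p.K437fs	frameshift_indel	T1;T2;T3
MSI-H1	TGFBR2	p.E125fs	frameshift_indel	T1;T2;T3
MSI-H2	APC	p.R1450X	nonsense	T1;T2;T3
MSI-H2	APC	p.Y158fs	frameshift_indel	T1;T2;T3
MSI-H2	SMARCA4	p.R885C	missense	T1;T2;T3
MSI-H2	SMARCA4	p.E861K	missense	T1;T2;T3
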