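gene	protein_change	count
SMARCA4	p.R1157W	23
SMARCA4	p.T910M	11
SMARCA4	p.R885C	14
SMARCA4	p.E861K	6
ERBB2	p.V842I	9
KRAS	p.G13D	1550
TP53	p.R273C	680
ATM	p.R2443Q	7
FBXW7	p.R465C	120
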