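snp_id	gene	effect_allele	other_allele	beta	se
rs1260326	GCKR	C	T	0.03	0.01
rs1481012	ABCG2	A	G	0.03	0.02
rs4410790	AHR	C	T	0.05	0.01
rs7800944	MLXIPL	C	T	0.06	0.02
rs17685	POR	A	G	0.05	0.01
rs6265	BDNF	C	T	0.03	0.01
rs2470893	CYP1A1	T	C	0.09	0.01
rs9902453	EFCAB5	G	A	0.03	0.01
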