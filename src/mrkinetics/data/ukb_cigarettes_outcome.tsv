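snp_id	gene	effect_allele	other_allele	beta	se
rs1260326	GCKR	C	T	-0.214	0.132
rs1481012	ABCG2	A	G	0.203	0.202
rs4410790	AHR	C	T	0.016	0.128
rs7800944	MLXIPL	C	T	-0.006	0.140
rs17685	POR	A	G	0.015	0.137
rs6265	BDNF	C	T	0.207	0.167
rs2470893	CYP1A1	T	C	0.076	0.135
rs9902453	EFCAB5	G	A	-0.144	0.125
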