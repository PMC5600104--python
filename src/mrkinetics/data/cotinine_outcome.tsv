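snp_id	gene	effect_allele	other_allele	beta	se
rs1260326	GCKR	C	T	-0.0102	0.0207
rs1481012	ABCG2	A	G	-0.0139	0.0323
rs4410790	AHR	C	T	0.0087	0.0208
rs7800944	MLXIPL	C	T	0.0114	0.0284
rs17685	POR	A	G	-0.0319	0.0258
rs6265	BDNF	C	T	0.0163	0.0262
rs2470893	CYP1A1	T	C	-0.0647	0.0284
rs9902453	EFCAB5	G	A	0.0002	0.0204
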