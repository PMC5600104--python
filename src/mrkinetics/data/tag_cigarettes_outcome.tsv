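snp_id	gene	effect_allele	other_allele	beta	se
rs1260326	GCKR	C	T	-0.0821	0.0826
rs1481012	ABCG2	A	G	0.0297	0.1355
rs4410790	AHR	C	T	-0.0679	0.0906
rs7800944	MLXIPL	C	T	-0.0881	0.0973
rs17685	POR	A	G	0.1387	0.1377
rs6265	BDNF	C	T	0.0465	0.1045
rs2470893	CYP1A1	T	C	-0.2125	0.0964
rs9902453	EFCAB5	G	A	-0.0642	0.0817
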