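entry_id	chain_id	receptor_id	ligand_class	notes
1U19	A	brh	inverse_agonist	representative inactivated chain
2Z73	A	srh	antagonist	representative inactivated chain
2RH1	A	b2	inverse_agonist	reference chain; T4L
2VT4	B	b1	antagonist	representative inactivated chain
3EML	A	A2A	antagonist	T4L
3ODU	A	CXCR4	antagonist	T4L
3PBL	A	D3	antagonist	T4L
3RZE	A	H1	antagonist	T4L
3UON	A	M2	antagonist	T4L
3V2Y	A	S1P1	antagonist	T4L
3PQR	A	brh	agonist	activated (Meta II)
3PXO	A	brh	agonist	activated (Meta II)
3SN6	R	b2	agonist	activated; Gs complex, Nb
3QAK	A	A2A	agonist	activated
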