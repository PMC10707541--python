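family	isotype	species	position	residue	ptm_type	evidence	provenance
alpha	α-1A	H. sapiens	54	S	PHO	validated	curated: synthesis-table PTM column
alpha	α-1A	H. sapiens	56	T	PHO	validated	curated: synthesis-table PTM column
alpha	α-1A	H. sapiens	60	K	ACE, UBI, SMO	validated	curated: synthesis-table PTM column
alpha	α-1A	H. sapiens	73	T	PHO	validated	curated: synthesis-table PTM column
alpha	α-1A	H. sapiens	158	S	PHO	validated	curated: synthesis-table PTM column
alpha	α-1A	H. sapiens	161	Y	PHO	validated	curated: synthesis-table PTM column
alpha	α-1A	H. sapiens	210	Y	PHO	validated	curated: synthesis-table PTM column
alpha	α-1A	H. sapiens	326	K	ACE, UBI, SMO	validated	curated: synthesis-table PTM column
alpha	α-1A	H. sapiens	336	K	ACE, UBI, SMO	validated	curated: synthesis-table PTM column
alpha	α-1A	H. sapiens	352	K	ACE, UBI, SMO	validated	curated: synthesis-table PTM column
alpha	α-1A	H. sapiens	394	K	ACE, UBI, SMO	validated	curated: synthesis-table PTM column
alpha	α-1A	H. sapiens	419	S	PHO	validated	curated: synthesis-table PTM column
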