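family	isotype	species	position	residue	ptm_type	evidence	provenance
beta	βI	H. sapiens	33	T	PHO	validated	curated: lost-modification column
beta	βI	H. sapiens	35	T	PHO	validated	curated: lost-modification column
beta	βI	H. sapiens	237	T	PHO	validated	curated: lost-modification column
beta	βI	H. sapiens	238	T	PHO	validated	curated: lost-modification column
beta	βI	H. sapiens	239	C	NIT, PAL	validated	curated: lost-modification column
beta	βI	H. sapiens	324	K	ACE, UBI	validated	curated: lost-modification column
beta	βI	H. sapiens	351	T	PHO	validated	curated: lost-modification column
beta	βIII	H. sapiens	166	T	PHO	validated	curated: lost-modification column
beta	βIII	H. sapiens	239	S	PHO	validated	curated: lost-modification column
beta	βIII	H. sapiens	297	K	ACE, UBI	validated	curated: lost-modification column
beta	βIII	H. sapiens	315	T	PHO	validated	curated: lost-modification column
beta	βIII	H. sapiens	335	S	PHO	validated	curated: lost-modification column
beta	βIII	H. sapiens	364	S	PHO	validated	curated: lost-modification column
beta	βIII	H. sapiens	365	S	PHO	validated	curated: lost-modification column
beta	βIII	H. sapiens	386	T	PHO	validated	curated: lost-modification column
beta	βIVB	H. sapiens	239	C	PAL	validated	curated: lost-modification column
beta	βIVB	H. sapiens	275	S	PHO	validated	curated: lost-modification column
beta	βIVB	H. sapiens	351	T	PHO	validated	curated: lost-modification column
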