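family	isotype	species	substitution	phenotype	provenance	ptm
alpha	α-1A	H. sapiens	S54N	Cerebellar dysplasia	PM 28677066	PHO
alpha	α-1A	H. sapiens	S54N	Tubulinopathies	CV 625506	PHO
alpha	α-1A	H. sapiens	S54R	Lissencephaly	CV 160150	PHO
alpha	α-1A	H. sapiens	T56M	Fetal tubulinopathy	PM 36403095	PHO
alpha	α-1A	H. sapiens	T56M	Lissencephaly	CV 625513	PHO
alpha	α-1A	H. sapiens	T56M	Microlissencephaly	PM 25059107	PHO
alpha	α-1A	H. sapiens	T56R	Cerebellar dysplasia	PM 33165829	PHO
alpha	α-1A	H. sapiens	K60N	Lissencephaly	CV 632599	ACE, UBI, SMO
alpha	α-1A	H. sapiens	T73A	Fetal tubulinopathy	PM 36403095	PHO
alpha	α-1A	H. sapiens	S158L	Fetal tubulinopathy	PM 36403095	PHO
alpha	α-1A	H. sapiens	S158L	Tubulinopathies	CV 625517	PHO
alpha	α-1A	H. sapiens	S158L	Polymicrogyria	PM 25059107	PHO
alpha	α-1A	H. sapiens	Y161D	Lissencephaly	CV 160158	PHO
alpha	α-1A	H. sapiens	Y161H	Tubulinopathies	CV 625477	PHO
alpha	α-1A	H. sapiens	Y161H	Polymicrogyria	PM 22948023	PHO
alpha	α-1A	H. sapiens	Y210C	Epileptic encephalopathy	PM 35892608	PHO
alpha	α-1A	H. sapiens	Y210C	Tubulinopathies	CV 625474	PHO
alpha	α-1A	H. sapiens	Y210C	Lissencephaly	PM 21403111	PHO
alpha	α-1A	H. sapiens	K326N	Tubulinopathies	CV 625487	ACE, UBI, SMO
alpha	α-1A	H. sapiens	K326N	Microlissencephaly	PM 25059107	ACE, UBI, SMO
alpha	α-1A	H. sapiens	K336R	Tubulinopathies	CV 625496	ACE, UBI, SMO
alpha	α-1A	H. sapiens	K352M	Tubulinopathies	CV 521592	ACE, UBI, SMO
alpha	α-1A	H. sapiens	K394N	Lissencephaly	CV 864867	ACE, UBI, SMO
alpha	α-1A	H. sapiens	S419L	Lissencephaly	CV 7074	PHO
alpha	α-1A	H. sapiens	S419L	Lissencephaly	PM 17584854	PHO
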