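family	isotype	species	substitution	phenotype	provenance
alpha	α-1A	H. sapiens	E155D	Brain malformations, mirror movements	PM 33413009
alpha	α-1A	H. sapiens	S158L	Fetal Tubulinopathy	PM 36403095
alpha	α-1A	H. sapiens	S158L	Polymicrogyria like cortical dysplasia	PM 25059107
alpha	α-1A	H. sapiens	Y161D	Lissencephaly, pathogenic	CV 160158
alpha	α-1A	H. sapiens	Y161H	Polymicrogyria	PM 22948023
alpha	α-1A	H. sapiens	I196L	Tubulinopathies	CV 625493
alpha	α-1A	H. sapiens	P263T	Lissencephaly	PM 18669490
alpha	α-1A	H. sapiens	P263T	Cortical malformations, lissencephaly	PM 17584854
alpha	α-1A	H. sapiens	R264C	Lissencephaly	PM 29671837
alpha	α-1A	H. sapiens	R264C	Cerebellar dysplasia	PM 28677066
alpha	α-1A	H. sapiens	R264C	Polymicrogyria, pachygyria	PM 18728072
alpha	α-1A	H. sapiens	R264C	Lissencephaly	PM 17218254
alpha	α-1A	H. sapiens	R264C	Cortical malformations, lissencephaly	PM 17584854
alpha	α-1A	H. sapiens	R264G	Tubulinopathies, pathogenic	CV 265283
alpha	α-1A	H. sapiens	R264H	Lissencephaly	CV 287392
alpha	α-1A	H. sapiens	R264H	Microlissencephaly	PM 25059107
alpha	α-1A	H. sapiens	R264P	Fetal Tubulinopathy	PM 36403095
alpha	α-1A	H. sapiens	A333V	Polymicrogyria	PM 23361065
alpha	α-1A	H. sapiens	K336R	Tubulinopathies	CV 625496
alpha	α-1A	H. sapiens	V336E	Tubulinopathies	CV 625514
alpha	α-1A	H. sapiens	M342V	Lissencephaly	CV 160142
alpha	α-1A	H. sapiens	Q342P	Tubulinopathies	CV 449112
alpha	α-1A	H. sapiens	A348D	Tubulinopathies	CV 427202
alpha	α-1A	H. sapiens	A348V	Lissencephaly	CV 160143
alpha	α-4A	H. sapiens	K430N	Familial ALS association	PM 25374358
alpha	α-1A	H. sapiens	D431G	Lissencephaly	PQ 2552055004
alpha	α-1A	H. sapiens	V435A	Lissencephaly	CV 437120
alpha	α-4AA	H. sapiens	D438N	Sporadic ALS risk	PM 25893256
beta	β	H. sapiens	L106F	Cortical dysplasia, other brain malformations	CV 807517
beta	β-3	H. sapiens	T106M	Cortical dysplasia	CV 265335
beta	β-4A	H. sapiens	T106M	Leukodystrophy	CV 267774
beta	β-4A	H. sapiens	T106R	Leukodystrophy	CV 139453
beta	β-4A	H. sapiens	P110T	Leukodystrophy, hypomyelinating	CV 267775
beta	β-2B	H. sapiens	P173L	Malformation of cortical development	PM 25059107
beta	β-3	H. sapiens	N175S	Cortical dysplasia, brain malformations	CV 160196
beta	β-3	H. sapiens	V175L	Hydrocephalus, Walker–Warburg Syndrome	PM 29187032
beta	β-3	H. sapiens	E205K	Malformation of cortical development	PM 20829227
beta	β-2A	H. sapiens	Q206P	Cortical dysplasia, brain malformations	CV 217024
beta	β-3	H. sapiens	A302T	Extraocular congenital fibrosis syndrome	PM 20074521
beta	β-3	H. sapiens	A302T	Infantile esotropia	PM 35765833
beta	β-3	H. sapiens	A302T	Fibrosis of extraocular muscles	CV 6964
beta	β-3	H. sapiens	A302V	Malformation of cortical development	PM 20829227
beta	β-3	H. sapiens	A302V	Cortical dysplasia	CV 30275
beta	β-4A	H. sapiens	M302L	Leukodystrophy	CV 537237
beta	β-2A	H. sapiens	R306C	Cortical dysplasia	CV 521900
beta	β-4A	H. sapiens	V306I	Leukodystrophy	CV 217025
beta	β	H. sapiens	P307L	Cortical dysplasia	CV 438586
beta	β-4A	H. sapiens	R307H	Leukodystrophy	CV 265314
beta	β-2A	H. sapiens	A308V	Cortical dysplasia	CV 800924
beta	β-4A	H. sapiens	M308L	Leukodystrophy	CV 537237
beta	β-3	H. sapiens	R380C	Congenital fibrosis of the extraocular muscles	PM 20074521
beta	β-2B	H. sapiens	R380C	Cortical malformations	PM 23361065
beta	β-3	H. sapiens	R380C	Cerebellar dysplasia	PM 28677066
beta	β-2B	H. sapiens	R380C	Cerebellar dysplasia	PM 28677066
beta	β-2B	H. sapiens	R380S	Cortical malformations	PM 23361065
beta	β-2B	H. sapiens	R390L	Bilateral ventriculomegaly	PM 36403095
beta	β-2B	H. sapiens	R390Q	Uner Tan syndrome	PM 28013290
beta	β-4B	H. sapiens	R391C	Leber congenital amaurosis	PM 29198720
beta	β-4B	H. sapiens	R391C	Ophthalmologic and hearing impairments	PM 35240325
beta	β-2A	H. sapiens	R391C	Cortical dysplasia	CV 521900
beta	β-4B	H. sapiens	R391H	Hypomyelination	PM 25085639
beta	β-4B	H. sapiens	R391H	Leber congenital amaurosis	PM 29198720
beta	β-4A	H. sapiens	R391L	Leukodystrophy	CV 419697
beta	β-2A	H. sapiens	H396Y	Tubulinopathy	PM 32571897
beta	β-4A	H. sapiens	A397S	Leukodystrophy	CV 807519
beta	β-4A	H. sapiens	A397T	Leukodystrophy	CV 267785
beta	β-4A	H. sapiens	C399W	Leukodystrophy	CV 453295
beta	β-4A	H. sapiens	C399Y	Leukodystrophy	CV 267786
beta	β-4A	H. sapiens	D400E	Leukodystrophy	CV 807518
beta	β	H. sapiens	E401K	Microcephaly	PM 23246003
beta	β	H. sapiens	E401K	Microcephaly	PM 30738969
beta	β	H. sapiens	E401K	Cortical dysplasia	CV 127191
beta	β-4A	H. sapiens	A403S	Leukodystrophy	CV 807519
beta	β-4A	H. sapiens	A403T	Leukodystrophy	CV 267785
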