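family	isotype	species	substitution	phenotype	provenance
alpha	α-1A	H. sapiens	T110A	Tubulinopathies	CV 625494
alpha	α-1A	H. sapiens	E113K	Tubulinopathies	CV 625503
alpha	α-1A	H. sapiens	C402Y	Lissencephaly, Hirschsprung disease	PM 23528852
alpha	α-1A	H. sapiens	R402C	Lissencephaly	PM 29671837
alpha	α-1A	H. sapiens	R402C	Lissencephaly	PM 18669490
alpha	α-1A	H. sapiens	R402C	Lissencephaly	PM 25059107
alpha	α-1A	H. sapiens	R402C	Lissencephaly	PM 20466733
alpha	α-1A	H. sapiens	R402C	Lissencephaly	PM 18954413
alpha	α-1A	H. sapiens	R402C	Lissencephaly	PM 17584854
alpha	α-1A	H. sapiens	R402H	Lissencephaly	PM 29671837
alpha	α-1A	H. sapiens	R402H	Lissencephaly	PM 25059107
alpha	α-1A	H. sapiens	R402H	Lissencephaly	PM 17218254
alpha	α-1A	H. sapiens	R402H	Lissencephaly	PM 20466733
alpha	α-1A	H. sapiens	R402H	Lissencephaly	PM 17584854
alpha	α-1A	H. sapiens	R402H	Malformations of cortical development	PM 35017693
alpha	α-1A	H. sapiens	R402L	Lissencephaly	PM 18954413
alpha	α-1A	H. sapiens	R402L	Lissencephaly	PM 22264709
alpha	α-1A	H. sapiens	R402S	Lissencephaly	CV 160145
alpha	α-1A	H. sapiens	H406D	Congenital fibrosis of the extraocular muscles	PM 33649541
alpha	α-1A	H. sapiens	H406Y	Fetal tubulinopathy	PM 36403095
alpha	α-4A	H. sapiens	W407X	Familial amyotrophic lateral sclerosis association	PM 25374358
alpha	α-1A	H. sapiens	V409A	Lissencephaly	PM 25059107
alpha	α-1A	H. sapiens	V409I	Tubulinopathies	CV 625504
alpha	α-1A	H. sapiens	E411G	Lissencephaly	CV 620053
alpha	α-1A	H. sapiens	G412R	Syndromic arthrogryposis multiplex congenita	PM 35686685
alpha	α-1A	H. sapiens	G416D	Lissencephaly	CV 591001
alpha	α-1A	H. sapiens	G416S	Tubulinopathies	CV 384538
beta	β-2A	H. sapiens	N162K	Cortical dysplasia	CV 127100
beta	β-2A	H. sapiens	A163V	Cortical dysplasia	CV 127101
beta	β-4A	H. sapiens	G163R	Leukodystrophy	CV 643798
beta	β-3	H. sapiens	T196A	Agenesis of the corpus callosum	PM 36403095
beta	β-2B	H. sapiens	L253P	Cortical malformations	PM 32570172
beta	β-3	H. sapiens	R262C	Extraocular congenital fibrosis syndrome	PM 20074521
beta	β-3	H. sapiens	R262H	Extraocular congenital fibrosis syndrome	PM 20074521
beta	β-3	H. sapiens	R262H	Extraocular congenital fibrosis syndrome	PM 24612975
beta	β-4A	H. sapiens	R262H	Hypomyelination (H-ABC)	PM 24706558
beta	β-4A	H. sapiens	R262H	Hypomyelinating leukoencephalopathy	PM 24850488
beta	β-2A	H. sapiens	R262H	Arthrogryposis multiplex congenita	PM 28840640
beta	β-4A	H. sapiens	R262H	Hypomyelination (H-ABC)	PM 24974158
beta	β-8	H. sapiens	R262Q	Defects in oocyte meiosis and female infertility	PM 26789871
beta	β-8	H. sapiens	R262W	Defects in oocyte meiosis and female infertility	PM 27273344
beta	β-8	H. sapiens	R262W	Defects in oocyte meiosis and female infertility	PM 36463079
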