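family	isotype	species	substitution	phenotype	provenance	lost_modification
beta	βI	H. sapiens	C239L*, I152T, L240P, R241P, L273P	Breast cancer isolate	Wang et al. (2017)	Nitrosylation/palmitoylation
beta	βI	H. sapiens	C239L*, T237H*, T238H*, L240P, R241P	Breast cancer isolate	Wang et al. (2017)	Nitrosylation/palmitoylation, phosphorylation
beta	βI	H. sapiens	C239Y*	Breast cancer isolate	Wang et al. (2017)	Nitrosylation/palmitoylation
beta	βI	H. sapiens	C239P*, L240P, R241P	Breast cancer isolate	Wang et al. (2017)	Nitrosylation/palmitoylation
beta	βI	H. sapiens	T238H*, C239L*, L240P, R241P	Breast cancer isolate	Wang et al. (2017)	Nitrosylation/palmitoylation, phosphorylation
beta	βI	H. sapiens	C239L*, L240P, R241P	Breast cancer isolate	Wang et al. (2017)	Nitrosylation/palmitoylation
beta	βI	H. sapiens	D177G, C239R*	Breast cancer isolate	Wang et al. (2017)	Nitrosylation/palmitoylation
beta	βI	H. sapiens	I155V, K324R*, L331H	Breast cancer isolate	Wang et al. (2017)	Acetylation/Ubiquitination
beta	βI	H. sapiens	L112P, T351V*, A364S, V365	Breast cancer isolate	Wang et al. (2017)	Phosphorylation
beta	βI	H. sapiens	T33S*, T35N*	Breast cancer isolate	Wang et al. (2017)	Phosphorylation
beta	βIIA	H. sapiens	E45D, N48S, V64I, V170M, C201S, A296S, V316I	Breast cancer isolate	Wang et al. (2017)	None
beta	βIII	H. sapiens	A275T	Breast cancer isolate	Wang et al. (2017)	None
beta	βIII	H. sapiens	V180A, T315A*, A332N, I333V, S335N*, V351T, S365A*, I374T	Breast cancer isolate	Wang et al. (2017)	Phosphorylation
beta	βIII	H. sapiens	I189V, A218T, A275S, Q291R, K297R*, R320P, S364A*, T386S*	Breast cancer isolate	Wang et al. (2017)	Acetylation/ubiquitination, phosphorylation
beta	βIII	H. sapiens	V170M	Breast cancer isolate	Wang et al. (2017)	None
beta	βIII	H. sapiens	D249E, M293V, T315A*, A332N, I333V, S335N*, V351T, A352V, S364A*, S365V*	Breast cancer isolate	Wang et al. (2017)	Phosphorylation
beta	βIII	H. sapiens	T166A*, I189V, S239C*, T315A*, A332N, I333V, S335N*, V351T	Breast cancer isolate	Wang et al. (2017)	Phosphorylation
beta	βIVB	H. sapiens	P171L, C239R*	Breast cancer isolate	Wang et al. (2017)	Palmitoylation
beta	βIVB	H. sapiens	V333I, N332A, N335S, T351V*, A365S	Breast cancer isolate	Wang et al. (2017)	Phosphorylation
beta	βIVB	H. sapiens	L44P, S275A*, Q292R, A315T, V333I, N332A, N335S, T351V*, A365S	Breast cancer isolate	Wang et al. (2017)	Phosphorylation
beta	βIVB	H. sapiens	E45D, N48S, V64I	Breast cancer isolate	Wang et al. (2017)	None
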