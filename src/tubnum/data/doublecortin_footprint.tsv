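structure_id	partner	family	positions	provenance
6RF2/6RF8	doublecortin	alpha	155, 158–163, 166, 195–197, 262–264, 333, 335–343, 345, 348, 430, 431, 434, 435, 438–441	PDB 6RF2/6RF8
6RF2/6RF8	doublecortin	beta	94, 95, 103, 106–108, 110, 111, 114, 173–175, 205, 206, 209, 213, 301–304, 306–308, 376, 380, 383, 384, 390–392, 395–397, 399–405, 426	PDB 6RF2/6RF8
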