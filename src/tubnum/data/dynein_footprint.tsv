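structure_id	partner	family	positions	provenance
3J1U	dynein	alpha	104, 108–110, 112, 113, 402, 403, 405–417, 420	PDB 3J1U
3J1U	dynein	beta	158, 162, 163, 196, 253, 261–264, 431, 434	PDB 3J1U
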