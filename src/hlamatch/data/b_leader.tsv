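# Curated HLA-B leader peptide position -21 residues (M = methionine,
# T = threonine) for the alleles used by the packaged pools and tests.
# Threonine is the majority variant, so the most common shared genotype in
# simulated cohorts is TTT, as in registry data.
allele	verdict
B*07:02	M
B*08:01	M
B*14:02	M
B*18:01	M
B*38:01	M
B*39:01	M
B*13:02	T
B*15:01	T
B*27:05	T
B*35:01	T
B*35:02	T
B*35:03	T
B*35:08	T
B*40:01	T
B*44:02	T
B*44:03	T
B*51:01	T
B*57:01	T
B*58:01	T
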