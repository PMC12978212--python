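# Curated peptide-binding-motif (PBM) groups: clusters of class I and
# HLA-DRB1 allotypes with overlapping immunopeptidomes. Group identifiers
# are internal labels; only equality between them is meaningful. Alleles
# with no primary immunopeptidomics data are deliberately absent (lookup
# yields "unknown" and classification NA). Allotypes sharing a P-group
# always share a PBM group, so ARD-matched implies PBM-matched.
allele	verdict
A*01:01	A-01
A*02:01	A-02
A*03:01	A-03
A*11:01	A-03
A*24:02	A-24
A*32:01	A-01
B*07:02	B-07
B*08:01	B-08
B*13:02	B-13
B*14:02	B-14
B*15:01	B-62
B*18:01	B-18
B*27:05	B-27
B*35:01	B-35
B*35:02	B-35
B*35:03	B-35
B*35:08	B-35
B*38:01	B-39
B*39:01	B-39
B*40:01	B-44
B*44:02	B-44
B*44:03	B-44
B*51:01	B-51
B*57:01	B-58
B*58:01	B-58
C*01:02	C-01
C*02:02	C-02
C*03:03	C-03
C*03:04	C-03
C*04:01	C-04
C*05:01	C-05
C*08:02	C-05
C*06:02	C-06
C*07:01	C-07
C*07:02	C-07
DRB1*01:01	DR-1
DRB1*15:01	DR-2
DRB1*16:01	DR-2
DRB1*03:01	DR-3
DRB1*04:01	DR-4
DRB1*04:04	DR-4
DRB1*11:01	DR-5
DRB1*11:04	DR-5
DRB1*13:01	DR-5
DRB1*13:02	DR-5
DRB1*07:01	DR-6
DRB1*08:01	DR-7
DRB1*14:01	DR-7
DRB1*14:54	DR-7
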