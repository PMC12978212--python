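# hla_nom_p dialect: locus*;allele[/allele...];[P-group]
# Curated miniature P-group table covering the alleles used by the packaged
# synthetic pools and the test suite. The file follows the IPD-IMGT/HLA
# hla_nom_p.txt format exactly so a full release file can be substituted.
# An empty third field marks a singleton allele (its own group).
A*;01:01:01:01/01:01:01:02N/01:01:02;01:01P
A*;02:01:01:01/02:01:01:02L/02:01:02;02:01P
A*;03:01:01:01/03:01:01:02N/03:01:04;03:01P
A*;11:01:01:01/11:01:02;11:01P
A*;24:02:01:01/24:02:01:02L/24:02:03;24:02P
A*;24:09N;
A*;26:01:01;26:01P
A*;32:01:01;32:01P
B*;07:02:01:01/07:02:02;07:02P
B*;08:01:01:01/08:01:02;08:01P
B*;13:02:01;13:02P
B*;14:02:01;14:02P
B*;15:01:01:01/15:01:01:02N;15:01P
B*;18:01:01:01/18:01:01:02;18:01P
B*;27:05:02/27:05:03;27:05P
B*;35:01:01:01/35:01:01:02/35:01:03;35:01P
B*;35:02:01;35:02P
B*;35:03:01;35:03P
B*;35:08:01;35:08P
B*;38:01:01;38:01P
B*;39:01:01:01;39:01P
B*;40:01:01/40:01:02;40:01P
B*;44:02:01:01/44:02:01:03;44:02P
B*;44:03:01:01;44:03P
B*;51:01:01:01/51:01:02/51:11N;51:01P
B*;57:01:01:01;57:01P
B*;58:01:01:01;58:01P
C*;01:02:01/01:02:02;01:02P
C*;02:02:02:01/02:02:02:02;02:02P
C*;03:03:01:01/03:03:01:02;03:03P
C*;03:04:01:01/03:04:01:02/03:04:02;03:04P
C*;04:01:01:01/04:01:01:05;04:01P
C*;05:01:01:01/05:01:01:02;05:01P
C*;06:02:01:01/06:02:01:02;06:02P
C*;07:01:01:01/07:01:02;07:01P
C*;07:02:01:01/07:02:01:03;07:02P
C*;08:02:01:01;08:02P
C*;12:03:01:01;12:03P
DRB1*;01:01:01;01:01P
DRB1*;03:01:01:01/03:01:01:02;03:01P
DRB1*;04:01:01:01;04:01P
DRB1*;04:04:01;04:04P
DRB1*;07:01:01:01/07:01:01:02;07:01P
DRB1*;08:01:01;08:01P
DRB1*;11:01:01:01/11:01:02;11:01P
DRB1*;11:04:01;11:04P
DRB1*;13:01:01:01;13:01P
DRB1*;13:02:01;13:02P
DRB1*;14:01:01/14:54:01;14:01P
DRB1*;15:01:01:01/15:01:01:02;15:01P
DRB1*;16:01:01;16:01P
DQB1*;02:01:01/02:02:01:01/02:02:01:02;02:01P
DQB1*;03:01:01:01/03:01:01:02/03:01:01:03;03:01P
DQB1*;03:02:01:01;03:02P
DQB1*;03:03:02:01/03:03:02:02;03:03P
DQB1*;05:01:01:01/05:01:01:02;05:01P
DQB1*;05:02:01;05:02P
DQB1*;06:02:01:01;06:02P
DQB1*;06:03:01:01;06:03P
DQB1*;06:04:01;06:04P
DQB1*;06:09:01;06:09P
DPB1*;01:01:01:01/01:01:02;01:01P
DPB1*;02:01:02/02:01:03;02:01P
DPB1*;02:02:01:01;02:02P
DPB1*;03:01:01:01/03:01:01:02;03:01P
DPB1*;04:01:01:01/04:01:01:02/105:01:01:01;04:01P
DPB1*;04:02:01:01/04:02:01:02;04:02P
DPB1*;05:01:01:01;05:01P
DPB1*;06:01:01:01;06:01P
DPB1*;09:01:01;09:01P
DPB1*;10:01:01:01;10:01P
DPB1*;11:01:01;11:01P
DPB1*;13:01:01:01;13:01P
DPB1*;14:01:01:01;14:01P
DPB1*;15:01:01:01;15:01P
DPB1*;16:01:01:01;16:01P
DPB1*;17:01:01:01;17:01P
DPB1*;19:01:01:01;19:01P
DPB1*;20:01:01:01;20:01P
DPB1*;23:01:01:01;23:01P
DPB1*;45:01:01;45:01P
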