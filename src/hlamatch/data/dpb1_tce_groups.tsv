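# Curated HLA-DPB1 T-cell epitope (TCE) group assignments (1 = most
# immunogenic) for the alleles used by the packaged pools and tests.
allele	verdict
DPB1*09:01	1
DPB1*10:01	1
DPB1*17:01	1
DPB1*03:01	2
DPB1*14:01	2
DPB1*45:01	2
DPB1*01:01	3
DPB1*02:01	3
DPB1*02:02	3
DPB1*04:01	3
DPB1*04:02	3
DPB1*05:01	3
DPB1*06:01	3
DPB1*11:01	3
DPB1*13:01	3
DPB1*15:01	3
DPB1*16:01	3
DPB1*19:01	3
DPB1*20:01	3
DPB1*23:01	3
DPB1*105:01	3
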