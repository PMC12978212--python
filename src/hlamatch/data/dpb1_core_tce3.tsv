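# Curated core vs non-core membership for TCE group-3 HLA-DPB1 alleles
# (core = structurally similar to the DPB1*04:01 family).
allele	verdict
DPB1*02:01	core
DPB1*02:02	core
DPB1*04:01	core
DPB1*04:02	core
DPB1*23:01	core
DPB1*105:01	core
DPB1*01:01	non-core
DPB1*05:01	non-core
DPB1*06:01	non-core
DPB1*11:01	non-core
DPB1*13:01	non-core
DPB1*15:01	non-core
DPB1*16:01	non-core
DPB1*19:01	non-core
DPB1*20:01	non-core
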