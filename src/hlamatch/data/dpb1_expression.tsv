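# Curated HLA-DPB1 expression linkage with the 3'UTR rs9277534 G/A
# polymorphism: G-linked alleles -> high expression, A-linked -> low.
allele	verdict
DPB1*02:01	low
DPB1*02:02	low
DPB1*04:01	low
DPB1*04:02	low
DPB1*23:01	low
DPB1*105:01	low
DPB1*01:01	high
DPB1*03:01	high
DPB1*05:01	high
DPB1*06:01	high
DPB1*09:01	high
DPB1*10:01	high
DPB1*11:01	high
DPB1*13:01	high
DPB1*14:01	high
DPB1*15:01	high
DPB1*16:01	high
DPB1*17:01	high
DPB1*19:01	high
DPB1*20:01	high
DPB1*45:01	high
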