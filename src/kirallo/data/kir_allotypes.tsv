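locus	allele	expression_class	residue_245	allele_group
KIR3DL1	*001	high
KIR3DL1	*002	high
KIR3DL1	*004	null
KIR3DL1	*005	low
KIR3DL1	*007	low
KIR3DL1	*008	high
KIR3DL1	*015	high
KIR3DL1	*020	high
KIR3DL1	*029	high
KIR3DL1	*038	high
KIR3DL1	*077	unknown
KIR2DL1	*001		R	*002/001g
KIR2DL1	*002		R	*002/001g
KIR2DL1	*003		R	*003
KIR2DL1	*004		C	*004g
KIR2DL1	*007		C	*004g
KIR2DL1	*034		R
KIR2DL1	*069		R
KIR2DL1	*0320102N			null-group
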