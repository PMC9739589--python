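GLUTAMINE_METABOLISM	9-gene glutamine-metabolism signature	ALDH18A1	GCLC	GCLM	GLS	GLUD1	GOT2	MTHFS	SLC38A1	SLC38A2
CYTOTOXICITY	CD8T cytotoxicity signature	GZMA	GZMB	PRF1	IFNG	EOMES	NKG7
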