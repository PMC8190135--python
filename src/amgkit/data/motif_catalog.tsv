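family	motif_id	pattern	description
DsrA	dsrA_substrate_R1	R	substrate binding arginine
DsrA	dsrA_substrate_KxKxK	KxKxK	substrate binding lysine triplet
DsrA	dsrA_substrate_R2	R	substrate binding arginine
DsrA	dsrA_substrate_HeR	HeR	substrate binding His-Glu-Arg
DsrA	dsrA_siroheme_CxgxxxC	CxgxxxC	siroheme binding cysteine pair
DsrA	dsrA_siroheme_CxxdC	CxxdC	siroheme binding cysteine pair
DsrC	dsrC_cys_conserved	CxxxgxpxpxxC	strictly conserved two-cysteine motif (residue-context spelling)
DsrC	dsrC_cys_spacing	CxxxxxxxxxxC	strictly conserved two-cysteine motif (spacing-only spelling)
SoxYZ	soxYZ_substrate_ggCs	ggCs	substrate-binding cysteine
SoxYZ	soxYZ_variable_CC	CC	variable cysteine motif
SoxC	soxC_active_XxH	XxH	cofactor coordination histidine
SoxC	soxC_active_D	D	active site aspartate
SoxC	soxC_active_R	R	active site arginine
SoxC	soxC_active_XxK	XxK	active site lysine
SoxD	soxD_cytc_CxxCHG	CxxCHG	cytochrome c motif 1
SoxD	soxD_cytc_CMxxC	CMxxC	cytochrome c motif 2
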