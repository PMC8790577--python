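IFNG_6gene	synthetic stand-in membership for the 6-gene interferon-gamma signature	CXCL10	CXCL9	HLA-DRA	IDO1	IFNG	STAT1
Inflammatory_13gene	synthetic stand-in membership for the 13-gene inflammatory signature	CCL5	CD2	CD3D	CD3E	CIITA	CXCL13	CXCR6	GZMK	HLA-DRA	HLA-E	IDO1	IL2RB	NKG7
Exhausted_CD8_9gene	synthetic stand-in membership for the 9-gene exhausted CD8 T-cell signature	BTLA	CD160	CD244	CTLA4	ENTPD1	HAVCR2	LAG3	PDCD1	TIGIT
Exhausted_CD8_3gene	synthetic stand-in membership for the 3-gene exhausted CD8 T-cell signature	HAVCR2	LAG3	PDCD1
Activated_stroma	synthetic stand-in membership for the activated stromal signature	COL1A1	COL1A2	COL3A1	COL5A2	FAP	FN1	POSTN	SPARC	SULF1	THBS2
Hypoxia	synthetic stand-in membership for the hypoxia signature	ADM	ALDOA	CDKN3	ENO1	LDHA	MIF	NDRG1	P4HA1	PGAM1	SLC2A1	TPI1	VEGFA
Cytolytic_activity	synthetic stand-in membership for the cytolytic activity signature	GZMA	PRF1
TAM	synthetic stand-in membership for the tumor-associated macrophage signature	CD163	CD68	CSF1R	MRC1	MSR1	SIGLEC1
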