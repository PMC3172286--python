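Focal adhesion	KEGG pathway	VWF	IGF1R	CCND1	COL4A1	JUN	MAPK3	RAF1	IGF1	HGF	PTEN	FN1
Toll-like receptor signaling pathway	KEGG pathway	FOS	TNF	JUN	MAPK3	IL12A	IL1B	STAT1
p53 signaling pathway	KEGG pathway	CDKN1A	CCND1	GADD45G	IGF1	PTEN	GADD45A
MAPK signaling pathway	KEGG pathway	FOS	TNF	JUN	GADD45G	MAPK3	RAF1	IL1B	GADD45A
B cell receptor signaling pathway	KEGG pathway	FOS	CD19	JUN	MAPK3	RAF1
Acute myeloid leukemia	KEGG pathway	CCND1	MAPK3	PML	RAF1
T cell receptor signaling pathway	KEGG pathway	FOS	TNF	JUN	MAPK3	RAF1
Chronic myeloid leukemia	KEGG pathway	CDKN1A	CCND1	MAPK3	RAF1
Jak-STAT signaling pathway	KEGG pathway	CCND1	SOCS3	IL12A	EPOR	STAT1
Cytokine-cytokine receptor interaction	KEGG pathway	TNF	IL12A	IL1B	EPOR	HGF	CXCL12
Hematopoietic cell lineage	KEGG pathway	TNF	CD19	IL1B	EPOR
ErbB signaling pathway	KEGG pathway	CDKN1A	JUN	MAPK3	RAF1
Natural killer cell mediated cytotoxicity	KEGG pathway	PRF1	TNF	MAPK3	RAF1
Cell cycle	KEGG pathway	CDKN1A	CCND1	GADD45G	GADD45A
NOD-like receptor signaling pathway	KEGG pathway	TNF	MAPK3	IL1B
Fc epsilon RI signaling pathway	KEGG pathway	TNF	MAPK3	RAF1
ECM-receptor interaction	KEGG pathway	VWF	COL4A1	FN1
Chemokine signaling pathway	KEGG pathway	MAPK3	RAF1	STAT1	CXCL12
GnRH signaling pathway	KEGG pathway	JUN	MAPK3	RAF1
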