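gene	node_class	lineage_tag
Pou5f1	pluripotency	none
Nanog	pluripotency	none
Sox2	pluripotency	none
Esrrb	pluripotency	none
Tcf3	pluripotency	none
Klf4	pluripotency	none
Klf2	pluripotency	none
Tbx3	pluripotency	none
Jarid2	pluripotency	none
Sall4	pluripotency	none
Nr0b1	pluripotency	none
Zfp281	pluripotency	none
Zfp42	pluripotency	none
Stat3	pluripotency	none
Myc	pluripotency	none
Cdx2	lineage	trophectoderm
Eomes	lineage	trophectoderm
Hand1	lineage	trophectoderm
Tead4	lineage	trophectoderm
Gata4	lineage	endoderm
Gata6	lineage	endoderm
Sox17	lineage	endoderm
Fgfr2	lineage	endoderm
T	lineage	mesoderm
Gli2	lineage	mesoderm
Ptpn11	lineage	mesoderm
Otx2	lineage	ectoderm
Fgf5	lineage	ectoderm
Ncam1	lineage	ectoderm
Rai1	lineage	ectoderm
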