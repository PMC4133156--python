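marker	lineage	upstream_regulator	sign
Cdx2	trophectoderm		
Eomes	trophectoderm		
Hand1	trophectoderm		
Tead4	trophectoderm		
Gata4	endoderm		
Gata6	endoderm		
Sox17	endoderm		
Fgfr2	endoderm		
T	mesoderm		
Gli2	mesoderm		
Ptpn11	mesoderm		
Otx2	ectoderm		
Fgf5	ectoderm		
Ncam1	ectoderm		
Rai1	ectoderm		
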