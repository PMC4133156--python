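# Synthetic stand-in for the 8 manually curated link refinements.
regulator	target	action	citation
Pou5f1	Hand1	-1	curated-lowthroughput
Pou5f1	Gata4	-1	curated-lowthroughput
Pou5f1	Ptpn11	-1	curated-lowthroughput
Nr0b1	Jarid2	-1	curated-lowthroughput
Tcf3	Nr0b1	-1	curated-lowthroughput
Sall4	Nr0b1	-1	curated-lowthroughput
Zfp42	Gata6	-1	curated-lowthroughput
Myc	Gli2	-1	curated-lowthroughput
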