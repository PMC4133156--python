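# Synthetic stand-in for the published 30-node mESC pluripotency
# network (no machine-readable edge list is available). Gene names
# and motif structure are realistic; exact wiring is constructed.
source	target	sign
Pou5f1	Pou5f1	+1
Pou5f1	Nanog	+1
Pou5f1	Sox2	+1
Pou5f1	Esrrb	+1
Pou5f1	Tcf3	+1
Pou5f1	Klf2	+1
Pou5f1	Tbx3	+1
Pou5f1	Jarid2	+1
Pou5f1	Sall4	+1
Pou5f1	Zfp42	+1
Pou5f1	Myc	+1
Pou5f1	Cdx2	-1
Pou5f1	Eomes	-1
Pou5f1	Hand1	-1
Pou5f1	Tead4	-1
Pou5f1	Gata4	-1
Pou5f1	Gli2	-1
Pou5f1	Ptpn11	-1
Pou5f1	Otx2	-1
Pou5f1	Fgf5	-1
Nanog	Pou5f1	+1
Nanog	Nanog	+1
Nanog	Sox2	+1
Nanog	Esrrb	+1
Nanog	Zfp281	+1
Nanog	Zfp42	+1
Nanog	Hand1	-1
Nanog	Gata4	-1
Nanog	Gata6	-1
Nanog	T	-1
Nanog	Fgf5	-1
Sox2	Pou5f1	+1
Sox2	Nanog	+1
Sox2	Sox2	+1
Sox2	Esrrb	+1
Sox2	Jarid2	+1
Sox2	Cdx2	-1
Sox2	Gata6	-1
Sox2	Gli2	-1
Sox2	Otx2	+1
Sox2	Ncam1	+1
Sox2	Rai1	+1
Esrrb	Pou5f1	+1
Esrrb	Nanog	+1
Esrrb	Sox2	+1
Esrrb	Esrrb	+1
Esrrb	Klf4	+1
Esrrb	Tbx3	+1
Esrrb	Nr0b1	+1
Esrrb	Cdx2	-1
Esrrb	Gata6	-1
Esrrb	T	-1
Esrrb	Otx2	-1
Esrrb	Ncam1	-1
Tcf3	Pou5f1	-1
Tcf3	Nanog	-1
Tcf3	Sox2	-1
Tcf3	Nr0b1	-1
Tcf3	Cdx2	+1
Tcf3	Gata6	+1
Tcf3	T	+1
Tcf3	Gli2	+1
Tcf3	Otx2	+1
Klf4	Nanog	+1
Klf4	Klf4	+1
Klf4	Klf2	+1
Klf4	Hand1	-1
Klf4	Gata4	-1
Klf4	Gata6	-1
Klf4	Fgfr2	-1
Klf2	Gata6	-1
Klf2	T	-1
Tbx3	Tbx3	+1
Tbx3	Gata4	+1
Tbx3	Gata6	+1
Tbx3	Fgf5	-1
Jarid2	Gata4	-1
Jarid2	Gata6	-1
Jarid2	Sox17	-1
Jarid2	T	-1
Sall4	Pou5f1	+1
Sall4	Sall4	+1
Sall4	Nr0b1	-1
Sall4	Gata4	-1
Sall4	Gata6	-1
Sall4	Sox17	-1
Nr0b1	Jarid2	-1
Nr0b1	Gata4	-1
Nr0b1	Gata6	-1
Zfp281	Nanog	-1
Zfp281	Gata4	+1
Zfp281	Sox17	+1
Zfp281	Fgfr2	+1
Zfp42	Zfp42	+1
Zfp42	Gata4	-1
Zfp42	Gata6	-1
Stat3	Klf2	+1
Stat3	Tbx3	+1
Stat3	Stat3	+1
Stat3	Myc	+1
Stat3	Hand1	-1
Stat3	T	-1
Myc	Myc	+1
Myc	Fgfr2	-1
Myc	Gli2	-1
Myc	Ncam1	-1
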