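canonical	arm	aliases
FLT1	lenvatinib	VEGFR1
KDR	lenvatinib	VEGFR2
FLT4	lenvatinib	VEGFR3
FGFR1	lenvatinib
FGFR2	lenvatinib
FGFR3	lenvatinib
FGFR4	lenvatinib
PDGFRA	lenvatinib	PDGFRa
PDGFRB	lenvatinib	PDGFRb
KIT	lenvatinib	c-kit,C-KIT
RET	lenvatinib
PDCD1	icb	PD-1,PD1
CD274	icb	PD-L1,PDL1
LAG3	icb	LAG-3
CTLA4	icb	CTLA-4
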