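symbol	modes	phenotype_groups
ABCA4	AR	STGD;CORD;MD;RP
BBS2	AR	BBS;RP
BEST1	AD	VMD;MD
CACNA1F	XL	CSNB;CORD
CEP290	AR	LCA;Joubert;BBS
CERKL	AR	RP
CHM	XL	choroideraemia
CNGA1	AR	RP
CNGB1	AR	RP
CNGB3	AR	CORD
CRB1	AR	RP;LCA
CRX	AD	CORD;LCA;RP
CYP4V2	AR	Bietti
ELOVL4	AD	STGD;MD
EYS	AR	RP
GUCY2D	AD;AR	CORD;LCA
IMPG2	AR	VMD;MD;RP
KLHL7	AD	RP
MERTK	AR	RP
MYO7A	AR	Usher;RP
NMNAT1	AR	LCA
NR2E3	AD;AR	RP
PDE6A	AR	RP
PDE6B	AR	RP;CSNB
PROM1	AD;AR	CORD;MD;RP;STGD
PRPF31	AD	RP
PRPF8	AD	RP
PRPH2	AD	RP;MD;VMD
RDH12	AR	LCA;RP
REEP6	AR	RP
RHO	AD	RP;CSNB
RLBP1	AR	RP
ROM1	AD	RP
RP1	AD;AR	RP;MD;CORD
RP1L1	AD	MD;CORD
RP2	XL	RP
RP9	AD	RP
RPE65	AR	LCA;RP
RPGR	XL	RP;CORD
SAG	AR	RP;CSNB
SNRNP200	AD	RP
SPATA7	AR	RP;LCA
TOPORS	AD	RP
TULP1	AR	RP;LCA
USH1C	AR	Usher
USH2A	AR	RP;Usher
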