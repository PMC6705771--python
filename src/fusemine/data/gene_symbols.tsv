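ABL	ABL
ABL1	ABL1
ABL2	ABL2
AFF1	AFF1
AKT1	AKT1
ALK	ALK
ATIC	ATIC
BCL2	BCL2
BCL6	BCL6
BCR	BCR
BRAF	BRAF
BTK	BTK
CCDC6	CCDC6
CRK	CRK
CRKL	CRKL
DDIT3	DDIT3|CHOP
EGFR	EGFR
EML4	EML4
ERG	ERG
ETV6	ETV6|TEL
EWS	EWS
EWSR1	EWSR1
FGFR1	FGFR1
FGFR3	FGFR3
FLI1	FLI1|FLI-1
FOXO1	FOXO1
FUS	FUS
GAB2	GAB2
GRB2	GRB2
GRB10	GRB10
HOXA9	HOXA9
JAK1	JAK1
JAK2	JAK2
JAK3	JAK3
KMT2A	KMT2A|MLL
KRAS	KRAS
MAP2K1	MAP2K1
MTOR	MTOR
MYB	MYB
MYC	MYC
NPM	NPM
NPM1	NPM1
NTRK1	NTRK1
NUP98	NUP98
PAX3	PAX3
PDGFRA	PDGFRA
PDGFRB	PDGFRB
PIK3CA	PIK3CA
PML	PML
PTPN11	PTPN11
RAF1	RAF1
RARA	RARA|RAR
RET	RET
ROS1	ROS1
RUNX1	RUNX1|AML1
SHC1	SHC1
SOS1	SOS1
SRC	SRC
SS18	SS18
SSX1	SSX1
STAT1	STAT1
STAT3	STAT3
STAT5	STAT5
STAT5B	STAT5B
SYK	SYK
TMPRSS2	TMPRSS2
TP53	TP53
TYK2	TYK2
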