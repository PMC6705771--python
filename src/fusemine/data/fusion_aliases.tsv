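BCR-ABL	BCR-ABL|BCR/ABL|BCR:ABL|BCR-ABL1|BCR/ABL1|BCR:ABL1
EWS-FLI1	EWS-FLI1|EWS/FLI1|EWS:FLI1|EWS/FLI-1|EWS-FLI-1|EWSR1-FLI1|EWSR1/FLI1|EWSR1:FLI1
TMPRSS2-ERG	TMPRSS2-ERG|TMPRSS2/ERG|TMPRSS2:ERG|TMRPSS2-ERG
NPM-ALK	NPM-ALK|NPM/ALK|NPM:ALK|NPM1-ALK
ATIC-ALK	ATIC-ALK|ATIC/ALK|ATIC:ALK
BCR-JAK2	BCR-JAK2|BCR/JAK2|BCR:JAK2
ETV6-RUNX1	ETV6-RUNX1|ETV6/RUNX1|ETV6:RUNX1|TEL-AML1
PML-RARA	PML-RARA|PML/RARA|PML:RARA|PML-RAR
EML4-ALK	EML4-ALK|EML4/ALK|EML4:ALK
FUS-DDIT3	FUS-DDIT3|FUS/DDIT3|FUS:DDIT3|FUS-CHOP
SS18-SSX1	SS18-SSX1|SS18/SSX1|SS18:SSX1
PAX3-FOXO1	PAX3-FOXO1|PAX3/FOXO1|PAX3:FOXO1
NUP98-HOXA9	NUP98-HOXA9|NUP98/HOXA9|NUP98:HOXA9
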