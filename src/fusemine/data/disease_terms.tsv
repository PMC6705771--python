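leukemia	leukemia|leukaemia|leukemias
chronic myeloid leukemia	chronic myeloid leukemia|chronic myelogenous leukemia|cml
acute lymphoblastic leukemia	acute lymphoblastic leukemia
lymphoma	lymphoma|lymphomas
anaplastic large cell lymphoma	anaplastic large cell lymphoma|alcl
sarcoma	sarcoma|sarcomas
ewing sarcoma	ewing sarcoma
prostate cancer	prostate cancer|prostate cancers
cancer	cancer|cancers|carcinoma|carcinomas|tumor|tumors|tumour|tumours
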