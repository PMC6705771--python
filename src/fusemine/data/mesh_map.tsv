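leukemia	D007938
chronic myeloid leukemia	D015464
acute lymphoblastic leukemia	D054198
lymphoma	D008223
anaplastic large cell lymphoma	D017728
sarcoma	D012509
ewing sarcoma	D012512
prostate cancer	D011471
cancer	D009369
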