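acute
cellular
chronic
clinical
constitutive
double
genomic
hematopoietic
human
large
medical
metastatic
molecular
murine
mutant
oncogenic
primary
recurrent
secondary
single
small
somatic
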