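norm	separator_to_hyphen	[–—:/]	-
norm	case_fold	[A-Z]+	lower
pattern	fusion_pair	[A-Za-z][A-Za-z0-9]*(?:[-–—/:][A-Za-z0-9]+)+	gene_a,gene_b
pattern	fusion_keyword	fusion|fusions|fusion genes|gene fusion|fusion protein|fusion proteins|fusion transcript|fusion transcripts	keyword
pattern	year_range	(?:19|20)[0-9]{2}[-–](?:19|20)[0-9]{2}	none
pattern	numeric	[0-9]+(?:\.[0-9]+)?	none
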