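fusion	fusion|fusions|fusion protein|fusion proteins|fusion gene|fusion genes|fusion transcript|fusion transcripts|gene fusion|gene fusions|fusion gene transcript|fusion gene transcripts|fusion oncogene|fusion oncogenes
chimera	chimera|chimeras|chimeric|chimeric protein|chimeric proteins|chimeric gene|chimeric genes|chimeric transcript|chimeric transcripts
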