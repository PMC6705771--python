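critical
effective
efficient
essential
important
novel
potent
promising
reliable
robust
significant
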