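# Motif spans excluded as ATP-binding sites by prior alanine-scanning
# mutagenesis of RyR1.
start	end	reason
2369	2377	mutagenesis
2370	2375	mutagenesis
3937	3940	mutagenesis
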