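# Membrane topology of rabbit RyR1 used for sidedness filtering. The
# transmembrane assembly occupies 3985-4937; the consensus motif at 4602-4607
# lies on the luminal face of that assembly. Positions not covered by any
# interval default to cytoplasmic.
start	end	compartment
3985	4601	transmembrane
4602	4607	luminal
4608	4937	transmembrane
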