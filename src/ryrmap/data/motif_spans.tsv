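# Published locations of nucleotide-binding consensus motifs in rabbit RyR1
# (1-based inclusive spans). WALKER_A = GXGXXG; WALKER_B_PARTIAL =
# [R/K]XXXGXXXL; GROES = Y[G/A/S/T][V/G][K/T/Q/S/N]. Where the source figure
# caption and the running text disagree (2126-2134 vs 2126-2234, 4449-4454 vs
# 4449-4452), the span whose length matches the pattern length is used.
pattern_id	start	end
WALKER_A	2	7
WALKER_A	699	704
WALKER_A	701	706
WALKER_A	1195	1200
WALKER_A	2264	2269
WALKER_A	2370	2375
WALKER_A	4449	4454
WALKER_A	4452	4457
WALKER_A	4602	4607
WALKER_B_PARTIAL	1302	1310
WALKER_B_PARTIAL	2126	2134
WALKER_B_PARTIAL	2369	2377
GROES	1081	1084
GROES	2935	2938
GROES	3503	3506
GROES	3937	3940
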