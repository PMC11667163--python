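# Linear chain: uptake -> two internal steps -> secretion (2 carbons).
u: A.ext (ab) -> A.c (ab)
v1: A.c (ab) -> B.c (ab)
v2: B.c (ab) -> C.out (ab)
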