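# Reversible interconversion with an unlabeled dilution inflow downstream.
u: A.ext (ab) -> A.c (ab)
x: A.c (ab) <-> B.c (ab)
d: N.dil (ab) -> B.c (ab)
s: B.c (ab) -> B.out (ab)
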