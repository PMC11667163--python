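# Diamond: two parallel routes from A to D, one of which flips the carbons.
u: S.ext (ab) -> A.c (ab)
v1: A.c (ab) -> D.c (ab)
v2: A.c (ab) -> D.c (ba)
s: D.c (ab) -> E.out (ab)
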