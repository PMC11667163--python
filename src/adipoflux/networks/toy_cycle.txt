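# Five-metabolite condensation cycle: acetyl-unit substrate condenses with a
# four-carbon acceptor, two decarboxylations per turn, symmetric four-carbon
# intermediate, unlabeled anaplerotic inflow and an efflux.
u: AC.ext (ab) -> ACC.c (ab)
cs: ACC.c (ab) + OAA.c (cdef) -> CIT.c (abcdef)
cl: CIT.c (abcdef) -> AKG.c (abcde) + CO2.out (f)
od: AKG.c (abcde) -> SUC.c (bcde) + CO2.out (a)
sd: SUC.c (abcd) <-> MAL.c (abcd)
md: MAL.c (abcd) -> OAA.c (abcd)
an: Y.ext (abcd) -> OAA.c (abcd)
ex: MAL.c (abcd) -> M.out (abcd)
#symmetric SUC.c
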