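# Core adipocyte carbon-transition network: glycolysis, oxidative PPP branch,
# TCA cycle with mitochondrial/cytosolic compartmentation, pyruvate cycling,
# glutamine/glutamate exchange with the medium, BCAA (leucine/valine/isoleucine)
# oxidation gated by BCKDH, propionyl-CoA anaplerosis, and fatty-acid synthesis
# sinks for C16:0 and the odd-chain species C15:0/C17:0.
#
# Compartments: ext = medium (boundary substrate), out = medium (boundary
# product), dil = unlabeled dilution pool, snk = product sink (unbalanced),
# c = cytosol, m = mitochondria.  Carbon numbering is 1-based from C1
# (first letter of each atom string = C1; pyruvate C1 = carboxyl).

# --- substrate uptake ---
v_glcup: GLC.ext (abcdef) -> GLC.c (abcdef)            # glucose uptake (measured rate)
v_glnup: GLN.ext (abcde) -> GLN.c (abcde)              # glutamine uptake from medium pool
v_gluup: GLU.ext (abcde) -> GLU.c (abcde)              # glutamate uptake from medium pool
v_leuup: LEU.ext (abcdef) -> LEU.c (abcdef)            # leucine uptake (measured rate)
v_valup: VAL.ext (abcde) -> VAL.c (abcde)              # valine uptake (measured rate)
v_ileup: ILE.ext (abcdef) -> ILE.c (abcdef)            # isoleucine uptake, always unlabeled

# --- glycolysis (lumped GLC -> 2 triose; no glycolytic intermediates measured) ---
v_gly: GLC.c (abcdef) -> GAP.c (cba) + GAP.c (def)     # aldolase carbon split C3-C2-C1 / C4-C5-C6
v_pk: GAP.c (abc) -> PYR.c (abc)                       # lower glycolysis, triose -> pyruvate
# oxidative PPP branch, flux fixed at 0.3% of glucose uptake (see #ratio below)
v_ppp: GLC.c (abcdef) -> CO2.out (a) + P5P.c (bcdef)   # G6PDH/6PGDH, C1 released as CO2
v_pppret: P5P.c (abcde) + P5P.c (fghij) + P5P.c (klmno) -> GLC.c (abcdef) + GLC.c (ghijkl) + GAP.c (mno)
    # non-oxidative return lumped (carbon-preserving aggregate mapping; flux is
    # pinned at 0.1% of uptake so the internal rearrangement is not resolvable)

# --- cytosolic pyruvate node ---
v_lac: PYR.c (abc) -> LAC.out (abc)                    # lactate secretion (measured rate)
v_ala: PYR.c (abc) -> ALA.out (abc)                    # alanine secretion (measured rate)
v_pyrt: PYR.c (abc) -> PYR.m (abc)                     # mitochondrial pyruvate carrier

# --- mitochondrial pyruvate / TCA cycle ---
v_pdh: PYR.m (abc) -> ACCOA.m (bc) + CO2.out (a)       # pyruvate dehydrogenase
v_pc: PYR.m (abc) + CO2.dil (d) -> OAA.m (abcd)        # pyruvate carboxylase, CO2 from unlabeled pool
v_me: MAL.m (abcd) -> PYR.m (abc) + CO2.out (d)        # malic enzyme (single lumped pool)
v_cs: ACCOA.m (ab) + OAA.m (cdef) -> CIT.m (abcdef)    # citrate synthase
v_idh: CIT.m (abcdef) -> AKG.m (fedba) + CO2.out (c)   # IDH; CO2 from the OAA-derived carboxyl
v_akgdh: AKG.m (abcde) -> SUC.m (bcde) + CO2.out (a)   # AKG dehydrogenase + SCS (SucCoA lumped)
v_sdh: SUC.m (abcd) -> FUM.m (abcd)                    # succinate dehydrogenase (symmetric pools)
v_fh: FUM.m (abcd) <-> MAL.m (abcd)                    # fumarase, reversible
v_mdh: MAL.m (abcd) <-> OAA.m (abcd)                   # mitochondrial malate dehydrogenase

# --- citrate shuttle and lipogenic acetyl-CoA ---
v_citt: CIT.m (abcdef) -> CIT.c (abcdef)               # citrate export
v_acl: CIT.c (abcdef) -> ACCOA.c (ab) + OAA.c (cdef)   # ATP-citrate lyase
v_mdhc: OAA.c (abcd) <-> MAL.c (abcd)                  # cytosolic malate dehydrogenase
v_malt: MAL.c (abcd) <-> MAL.m (abcd)                  # malate carrier (exchange per model assumptions)

# --- glutamine / glutamate ---
v_glnt: GLN.c (abcde) <-> GLN.m (abcde)                # glutamine carrier (exchange)
v_gls: GLN.m (abcde) -> GLU.m (abcde)                  # glutaminase
v_gdh: GLU.m (abcde) <-> AKG.m (abcde)                 # GDH/transaminase lump, reversible
v_glut: GLU.c (abcde) <-> GLU.m (abcde)                # glutamate carrier (exchange)
v_gs: GLU.c (abcde) -> GLN.c (abcde)                   # glutamine synthetase
v_glnsec: GLN.c (abcde) -> GLN.out (abcde)             # glutamine secretion to medium
v_glusec: GLU.c (abcde) -> GLU.out (abcde)             # glutamate secretion to medium

# --- BCAA oxidation (BCKDH-gated) ---
v_leut: LEU.c (abcdef) -> KIC.c (abcdef)               # BCAT, leucine -> ketoisocaproate
v_bckdh_leu: KIC.c (abcdef) + CO2.dil (g) -> CO2.out (a) + ACCOA.m (bc) + ACCOA.m (de) + ACCOA.m (gf)
    # BCKDH + downstream leucine oxidation lumped: C1 lost at BCKDH, MCC fixes
    # one unlabeled CO2, HMG-CoA lyase + ketolysis yield three acetyl-CoA
v_valt: VAL.c (abcde) -> KIV.c (abcde)                 # BCAT, valine -> ketoisovalerate
v_bckdh_val: KIV.c (abcde) -> CO2.out (a) + CO2.out (b) + PROPCOA.m (cde)
    # BCKDH + valine oxidation lumped to propionyl-CoA, two decarboxylations
v_ilet: ILE.c (abcdef) -> CO2.out (a) + ACCOA.m (bc) + PROPCOA.m (def)
    # isoleucine oxidation lumped: unlabeled AcCoA + PropCoA source
v_pcc: PROPCOA.m (abc) + CO2.dil (d) -> SUC.m (abcd)   # propionyl-CoA carboxylase -> SucCoA anaplerosis
v_propt: PROPCOA.m (abc) -> PROPCOA.c (abc)            # propionyl-CoA to cytosol for OCFA priming
v_mmasec: PROPCOA.m (abc) -> MMA.out (abc)             # propionyl overflow (B12-limited cultures
    # carboxylate little propionyl-CoA; excess leaves as short acids/acylcarnitines)

# --- fatty-acid synthesis sinks (measured FA products) ---
v_fas16: ACCOA.c (ab) + ACCOA.c (cd) + ACCOA.c (ef) + ACCOA.c (gh) + ACCOA.c (ij) + ACCOA.c (kl) + ACCOA.c (mn) + ACCOA.c (op) -> C16.snk (abcdefghijklmnop)
    # palmitate synthesis: 8 acetyl-CoA units
v_fas15: PROPCOA.c (abc) + ACCOA.c (de) + ACCOA.c (fg) + ACCOA.c (hi) + ACCOA.c (jk) + ACCOA.c (lm) + ACCOA.c (no) -> C15.snk (abcdefghijklmno)
    # C15:0 synthesis: 1 propionyl-CoA primer + 6 acetyl-CoA
v_fas17: PROPCOA.c (abc) + ACCOA.c (de) + ACCOA.c (fg) + ACCOA.c (hi) + ACCOA.c (jk) + ACCOA.c (lm) + ACCOA.c (no) + ACCOA.c (pq) -> C17.snk (abcdefghijklmnopq)
    # C17:0 synthesis: 1 propionyl-CoA primer + 7 acetyl-CoA

# --- annotations ---
#symmetric SUC.m
#symmetric FUM.m
#dilution CO2.dil
#dilution GLN.ext
#dilution GLU.ext
#ratio v_ppp v_glcup 0.003
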