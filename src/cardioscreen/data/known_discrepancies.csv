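peak_no,kind,note
2,printed_error_mismatch,"printed error -1.9 ppm; recomputed [M-H]- error for C12H22O11 vs 341.1089 is -0.1 ppm"
10,unverifiable,"detected m/z 718.2728 inconsistent with printed formula C49H82O3 (neutral mass 718.626) under either adduct; error column printed as None"
16,name_formula_conflict,"formula C32H24O3 has implausible ring-double-bond count for a glycoside losing Glc; detected mass verifies numerically"
29,name_formula_conflict,"2,2,6-trimethylcyclohexanone is C9H16O, not the printed C9H16O4; detected mass verifies against the printed formula"
35,name_formula_conflict,"C32H20O is chemically implausible (RDBE 23); mass arithmetic nevertheless verifies against the printed formula"
36,name_formula_conflict,"C32H18 (pure hydrocarbon, RDBE 24) implausible for this matrix; mass arithmetic verifies against the printed formula"
58,source_conflict,"notoginsenoside-type name but source printed as DS rather than SQ, leaving 26 SQ rows against the stated 27 Notoginseng compounds"
66,name_formula_conflict,"lobetyol is C14H18O2, printed formula C14H18O; detected column holds the [M-H+FA]- adduct m/z and verifies against the printed formula"
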