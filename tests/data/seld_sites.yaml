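# Functional-site spec for the synthetic SelD/SelD-like fixture alignment.
# Positions are ungapped positions of the reference row SelD_A; the letters
# listed under "allowed" count as conserved (catalytic Sec/Cys accepts U or C).
residues:
  - {name: catalytic_sec_cys, reference: SelD_A, position: 5, allowed: CU}
  - {name: asp_1, reference: SelD_A, position: 12, allowed: D}
  - {name: asp_2, reference: SelD_A, position: 15, allowed: D}
  - {name: asp_3, reference: SelD_A, position: 22, allowed: D}
  - {name: asp_4, reference: SelD_A, position: 30, allowed: D}
  - {name: conserved_asn, reference: SelD_A, position: 18, allowed: N}
motifs:
  - {name: sec_cys_x_x_lys, pattern: "[CU]xx[K]"}
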