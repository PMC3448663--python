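# Curated synthetic anchor profile, version 1.
#
# The reference sequences below are synthetic: they are not real DsrB/FrhB
# sequences but carry the same layout of functional signatures — four
# siroheme-coupling Cys anchors, four peripheral [Fe4-S4] Cys anchors, four
# sulfite-binding Arg/Lys positions numbered from the N-terminus, and one
# additional ferredoxin-type Cys motif between the peripheral block and the
# C-terminus. Anchor coordinates in this file are the authoritative
# definition of "signature present" for the classifier; swapping in a real
# curated DsrB reference with its own coordinates is the supported route to
# real-sequence use.
#
# The non-conserved cysteine that couples the cluster to siroheme in some
# DsrB proteins is deliberately NOT an anchor here: only the four conserved
# Cys positions count toward siroheme-site presence.
#
# Dsr-like reference layout (1-based):
#   SB1 R41, SB2 K71, SB3 R101, SB4 K160
#   siroheme Cys: 120, 125, 136, 141   (C-x4-C-x10-C-x4-C)
#   peripheral Cys: 190, 195, 200, 203 (C-x4-C-x4-C-x2-C)
#   additional ferredoxin motif: 230-240 (C-x2-C-x2-C-x3-C)
# The FrhB-core reference is cysteine-free so that ferredoxin-motif scanning
# around a detected core never picks up core residues.
version: 1
dsr_reference:
  id: DSR_REF_V1
  organism: synthetic
  sequence: MMYDHHQGERANDEEWVEDYRITWANDHLRVRPASKNDWGRDPAFDHTSGIPIITAEGSQEMWAFIINVNKAHPNTEDTPPSMTDGEPGPGVWFKWHWTERGRKTEPRGIYAPVLFNVYCWIVECQLSFGIIALVCSMPQCRLAKNPGEYHIQQAHEGWKRDQTHQGELWMGGFHPQIGSWIIEFANPLCQNWDCLLQECNWCFRHEEFQFTIMNSVRARANYAMEYPNCAACPPCAAACITNDAAGKDHRVEPSYPPLLPMPQDRNHAQITPPGITHSFIFPEWAMSQFENYAHR
frh_reference:
  id: FRH_REF_V1
  organism: synthetic
  sequence: NQQTWGGDMYNDKDRPPHEMPIRYAMIDWLINMGQVIANSNYMDALNHSANKERGQLFFNQNERMQRLLAHKRHGHKPDNAEPQIQHVKVWQFFWMTHAGSMYFPTMWVMTAHVQHVHNKVLLKIGVWENRGQGVTANAN
anchor_sites:
  - {site_id: SIROHEME_C1, feature_tag: SIROHEME_C1, ref_position: 120, allowed_residues: C}
  - {site_id: SIROHEME_C2, feature_tag: SIROHEME_C2, ref_position: 125, allowed_residues: C}
  - {site_id: SIROHEME_C3, feature_tag: SIROHEME_C3, ref_position: 136, allowed_residues: C}
  - {site_id: SIROHEME_C4, feature_tag: SIROHEME_C4, ref_position: 141, allowed_residues: C}
  - {site_id: PERIPHERAL_C1, feature_tag: PERIPHERAL_C1, ref_position: 190, allowed_residues: C}
  - {site_id: PERIPHERAL_C2, feature_tag: PERIPHERAL_C2, ref_position: 195, allowed_residues: C}
  - {site_id: PERIPHERAL_C3, feature_tag: PERIPHERAL_C3, ref_position: 200, allowed_residues: C}
  - {site_id: PERIPHERAL_C4, feature_tag: PERIPHERAL_C4, ref_position: 203, allowed_residues: C}
  - {site_id: SB1, feature_tag: SB1, ref_position: 41, allowed_residues: RK}
  - {site_id: SB2, feature_tag: SB2, ref_position: 71, allowed_residues: RK}
  - {site_id: SB3, feature_tag: SB3, ref_position: 101, allowed_residues: RK}
  - {site_id: SB4, feature_tag: SB4, ref_position: 160, allowed_residues: RK}
ferredoxin_motif:
  # Cys spacing gaps (min, max) between the four cysteines: C-x(2)-C-x(2)-C-x(3)-C
  gap1: [2, 2]
  gap2: [2, 2]
  gap3: [3, 3]
core_score_threshold: 0.5
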