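locus_id: toyLQTS
sequence: GTCACCATGGGCCACCCGAGGCAGAAAACTTGACATCACTGTCGATGACGCACACCATCAGAGATATCAACCGTACTAGTCTATCCTCAAGTACTCTAGTCCCTTACTGACGATGCAGGTTCACCCCTACGACGGGTTTGTCCTAAAGCCCGCTGCGGAATCAGGATTTCAGGAGTCGAAATTTCTCGCGAGAGCTTATTGAACATAGTTACTTAGTTTT
cut_index: 110
pam_side: right
primer_fwd_len: 20
primer_rev_len: 20
markers:
  - {offset_bp: 1, ref_base: A, alt_base: G, role: SYNONYMOUS}
  - {offset_bp: 3, ref_base: T, alt_base: C, role: SYNONYMOUS}
  - {offset_bp: 5, ref_base: A, alt_base: G, role: KI}
  - {offset_bp: 6, ref_base: T, alt_base: C, role: SYNONYMOUS}
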