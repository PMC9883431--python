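locus_id: toyBrS
sequence: AGCATTGAGAGGCGGAGTGGGAATGACCTCTTTGGGTGAGTAAGACACAAGACAATCGGGATCGCACTCCATGTATCCCGTGCGGTGGTATGGGTTCTAGGAGTGACAGACTATTTCTCTCACGGAACAGTAGTGAGAACCATAATAAACCTGCCTACTTACCGCGTTATAGCATATGCCTAGTTTCTGAACGCTGCAAGTAACGTATTTCAGCACAAGC
cut_index: 110
pam_side: left
primer_fwd_len: 20
primer_rev_len: 20
markers:
  - {offset_bp: 1, ref_base: C, alt_base: T, role: SYNONYMOUS}
  - {offset_bp: 8, ref_base: T, alt_base: C, role: KI}
  - {offset_bp: 12, ref_base: A, alt_base: G, role: SYNONYMOUS}
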