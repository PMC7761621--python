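# Example simulation: deamidation of the seven N/Q sites observed on the
# VDAC1-like scaffold, three replicates, tryptic digestion with up to three
# missed cleavages.  Occupancies are the deamidated/unmodified intensity
# ratios of the study converted to fractions, r / (1 + r).
proteins_fasta: builtin:vdac
enzyme: trypsin
max_missed_cleavages: 3
min_length: 6
max_length: 30
site_occupancy:
  - {protein: VDAC1_SYN, position: 37, modification: deamidation, probability: 0.020}
  - {protein: VDAC1_SYN, position: 106, modification: deamidation, probability: 0.010}
  - {protein: VDAC1_SYN, position: 166, modification: deamidation, probability: 0.002}
  - {protein: VDAC1_SYN, position: 207, modification: deamidation, probability: 0.375}
  - {protein: VDAC1_SYN, position: 214, modification: deamidation, probability: 0.038}
  - {protein: VDAC1_SYN, position: 226, modification: deamidation, probability: 0.002}
  - {protein: VDAC1_SYN, position: 239, modification: deamidation, probability: 0.029}
intensity_mean_log: 16.0
intensity_sigma_log: 1.0
peptide_location_sd: 1.0
charges: [0.1, 0.6, 0.3]
replicates: [G93A_rep1, G93A_rep2, G93A_rep3]
psms_per_peptide: 20
missing_rate: 0.0
seed: 1218
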