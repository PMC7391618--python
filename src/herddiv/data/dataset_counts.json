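{
  "description": "Dataset-level counts of the 115-breed cattle panel the reference table was published with.",
  "n_individuals_genotyped": 3457,
  "n_individuals_retained": 2858,
  "n_snps_post_qc": 46678,
  "n_blocks": 5756,
  "n_breeds": 115,
  "n_common_alleles": 590,
  "n_total_alleles": 80720
}
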