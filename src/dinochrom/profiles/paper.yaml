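# Full-scale analysis profile: the parameter set used for the published-scale
# analysis (40-kb karyotype bins, 10-kb insulation bins, 500-kb window,
# strength floor 0.2, 3-Mb rod cutoff, +/-500-kb pileups).
seed: 0
outdir: dinochrom_paper_out
resolution: 10000
insulation_window: 500000
delta_span: 100000
strength_min: 0.2
pileup_flank: 500000
simulate:
  n_chromosomes: 8
  chrom_length: 10000000
  domain_size: 2500000
  alpha: -0.4
  d_max: 3000000
  beta: 0.5
  tau: 2.0
  n_pairs: 5000000
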