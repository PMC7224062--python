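# Demonstration run: small duplicated locus, one het + one mosaic variant,
# an exon 8-9 deletion on MLPA, and a simulated cohort.
seed: 7
locus:
  length: 4000
  n_paralogs: 6
  identity: 0.98
  n_exons: 3
  exon_length: 300
amplicons:
  amplicon_length: 900
  min_overlap: 250
reads:
  depth: 200
  contamination: 0.05
  scenarios:
    - position: 350
      ref: auto
      alt: auto
      zygosity: het
      name: demo_het
    - position: 1900
      ref: auto
      alt: auto
      zygosity: mosaic
      mosaic_fraction: 0.16
      name: demo_mosaic
call:
  threshold: 0.10
  mosaic: true
mlpa:
  n_exons: 12
  copy_state:
    exon8: 1
    exon9: 1
cohort:
  n: 120
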