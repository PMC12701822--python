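# Demo pipeline: synthetic two-chromosome genome, all stages.
seed: 7
genome: [[chr1, 30000000], [chr2, 30000000]]
stages: [simulate, hic, insulation, chip, boundary, bands]
simulation:
  n_sites: 12
  min_separation: 3000000
  contact_bin_size: 50000
analysis:
  n_controls: 40
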