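# SYNTHETIC example config for the out-of-Africa admixture topology.
# Sizes on the varied axes match the published variant grids; the times
# and proportion are realistic-magnitude placeholders, NOT inferred
# posterior values. Supply your own inferred parameters for analysis.
admixtures:
- child: AMR
  parent_a: AFR
  parent_b: EUR
  proportion: 0.85
  time: 8340
founding_sizes:
  AMR: 61659
  EUR: 16982
migrations: []
name: admixture_synthetic
populations:
- epochs:
  - growth_rate: 0.0
    size: 4975360
    start_time: 0
  name: AFR
- epochs:
  - growth_rate: 0.0
    size: 700000
    start_time: 0
  name: EUR
- epochs:
  - growth_rate: 0.0
    size: 1110000
    start_time: 0
  name: AMR
reference_size: 4975360
sample_population: AMR
splits:
- child: EUR
  parent: AFR
  time: 510000
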