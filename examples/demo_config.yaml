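# Demo pipeline configuration: a small synthetic world of wild and
# managed goat populations.  Runs end-to-end in well under a minute.
seed: 20
n_sites: 20000
chrom_lengths:
  "1": 50000000
  "2": 50000000
coverage: 2.0
base_error: 0.00002
het_rate: 0.001
tree:
  - {name: ancestral, parent: null}
  - {name: bezoar_west, parent: ancestral, drift: 0.02}
  - {name: bezoar_east, parent: ancestral, drift: 0.02}
  - {name: zagros, parent: bezoar_east, drift: 0.03}
  - {name: domestic, parent: bezoar_east, drift: 0.03}
n_individuals:
  bezoar_west: 3
  bezoar_east: 3
  zagros: 3
  domestic: 3
admixture_edges:
  - {source: bezoar_west, dest: domestic, proportion: 0.2}
roh_tracts:
  zagros0:
    - {chrom: "1", start: 20000001, end: 28000000}
roh:
  x_length: 120000000
  n_males: 3
relatedness:
  bootstraps: 25
mt:
  contamination: 0.02
  coverage: 500
stages: [simulate, ascertain, pseudohaploid, roh, fstats, relatedness, mt]
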