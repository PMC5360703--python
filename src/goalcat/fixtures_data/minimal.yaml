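name: minimal
kind: structure_config
doc: >
  Every cardinality at its categorical minimum of two, with two flat features.
  At these values the flat-vs-latent decision threshold on the latent
  cardinality equals exactly 2, so a two-state latent can only tie the flat
  structure, never beat it.
payload:
  F: 2
  n_f: 2
  F1: 2
  F2: 2
  n_f1: 2
  n_f2: 2
  n_L1: 2
  n_L2: 2
  n_c: 2
  n_a: 2
  n_g: 2
  epsilon: 0.1
oracles:
  - name: flat_vs_latent_threshold
    value: 2.0
    provenance: literature
  - name: flat_characteristic_cells
    value: 16
    provenance: computed
    procedure: cell enumeration over the goal block of the constructed flat model (2^2 * 2 * 2)
  - name: latent_characteristic_cells
    value: 16
    provenance: computed
    procedure: cell enumeration over the feature and goal blocks of the constructed latent model (2^2*2 + 2*2*2)
  - name: latent_vs_hierarchical_threshold
    value: 3.0
    provenance: computed
    procedure: n_f1^F1 * (n_f2^F2 - 1) / n_f2^F2 at these values = 4*3/4
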