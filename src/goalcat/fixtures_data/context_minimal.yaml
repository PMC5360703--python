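name: context_minimal
kind: structure_config
doc: >
  Minimal cardinalities for the context comparison: two binary low-order
  features, a two-state content latent, binary context, action and goal.
  Folding the context into the latent costs 64 characteristic cells; keeping
  an explicit context variable costs 24.
payload:
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
  - name: context_folded_characteristic_cells
    value: 64
    provenance: literature
  - name: explicit_context_characteristic_cells
    value: 24
    provenance: literature
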