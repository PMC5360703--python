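name: animal_hierarchy
kind: structure_config
doc: >
  The worked hierarchy example: categorize an animal from noisy observations
  of five binary features (head, body, teeth, nails, limbs). Teeth, nails and
  limbs (the high-order subset, F2=3) suffice to separate herbivores from
  carnivores (the high-order latent); head and body (F1=2) refine the
  classification to the animal identity (the low-order latent, two states).
payload:
  F1: 2
  F2: 3
  n_f1: 2
  n_f2: 2
  n_L1: 2
  n_L2: 2
  n_c: 2
  n_a: 2
  n_g: 2
  epsilon: 0.1
oracles:
  - name: single_latent_characteristic_cells
    value: 64
    provenance: literature
  - name: hierarchical_characteristic_cells
    value: 40
    provenance: literature
  - name: hierarchy_threshold
    value: 3.5
    provenance: literature
  - name: latent_action_goal_cells
    value: 8
    provenance: computed
    procedure: cell enumeration of the goal block P(g | l1, a), 2*2*2
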