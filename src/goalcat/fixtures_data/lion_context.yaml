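name: lion_context
kind: world_spec
doc: >
  Deterministic contextual world: latent 0 = prey animal, 1 = lion; context
  0 = wild, 1 = zoo; action 0 = approach, 1 = escape. The goal is attained by
  escaping a lion in the wild and approaching in every other case. Features
  and observations are noiseless, so exact planning-as-inference must pick
  the context-appropriate action with posterior probability one.
payload:
  kind: contextual
  seed: 0
  cfg:
    F1: 2
    F2: 2
    n_f1: 2
    n_f2: 2
    n_L1: 2
    n_L2: 2
    n_c: 2
    n_a: 2
    n_g: 2
    epsilon: 0.0
  determinism:
    feature_slack: 0.0
    goal_success: 1.0
    goal_fail: 0.0
    coupling: 1.0
    low_patterns: [[0, 0], [1, 1]]
    high_patterns: [[0, 0], [1, 1]]
  goal_rule:
    type: correct_action
    table: [[0, 0], [1, 0]]
oracles:
  - name: best_action_lion_wild
    value: 1
    provenance: computed
    procedure: exact conditioning on the deterministic tables with o1=(1,1), oc=0, g clamped attained
  - name: best_action_lion_zoo
    value: 0
    provenance: computed
    procedure: exact conditioning with o1=(1,1), oc=1
  - name: best_action_prey_wild
    value: 0
    provenance: computed
    procedure: exact conditioning with o1=(0,0), oc=0
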