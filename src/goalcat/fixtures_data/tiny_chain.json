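{
 "name": "tiny_chain",
 "kind": "model",
 "doc": "Hand-built three-variable chain x -> y -> z with pinned tables; joint probabilities below were multiplied out by hand and double-checked by full-table enumeration.",
 "payload": {
  "variables": [
   {"name": "x", "role": "feature", "cardinality": 2},
   {"name": "y", "role": "observation", "cardinality": 2},
   {"name": "z", "role": "observation", "cardinality": 2}
  ],
  "blocks": [
   {"name": "prior_x", "children": ["x"], "parents": [], "table": [0.3, 0.7], "tags": []},
   {"name": "y_given_x", "children": ["y"], "parents": ["x"], "table": [0.9, 0.2, 0.1, 0.8], "tags": []},
   {"name": "z_given_y", "children": ["z"], "parents": ["y"], "table": [0.6, 0.5, 0.4, 0.5], "tags": []}
  ],
  "metadata": {"structure": "tiny_chain"}
 },
 "oracles": [
  {"name": "joint_x0_y0_z0", "value": 0.162, "provenance": "computed", "procedure": "0.3 * 0.9 * 0.6"},
  {"name": "joint_x1_y1_z0", "value": 0.28, "provenance": "computed", "procedure": "0.7 * 0.8 * 0.5"},
  {"name": "joint_x0_y1_z1", "value": 0.015, "provenance": "computed", "procedure": "0.3 * 0.1 * 0.5"}
 ]
}
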