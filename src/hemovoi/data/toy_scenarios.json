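{
  "schema_version": 1,
  "description": "Toy EVPI scenarios with equally weighted parameter states; net benefit per strategy per state in EUR. The analytic EVPI is recomputed by enumeration at load time (two_point -> 5, dominated -> 0, single_state -> 0).",
  "scenarios": {
    "two_point": {
      "strategies": ["A", "B"],
      "nb_matrix": [[0, 10], [0, -10]]
    },
    "dominated": {
      "strategies": ["A", "B"],
      "nb_matrix": [[0, 5], [2, 7], [-3, 1]]
    },
    "single_state": {
      "strategies": ["A", "B"],
      "nb_matrix": [[3, 7]]
    }
  }
}
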