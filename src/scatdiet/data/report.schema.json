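{
  "type": "object",
  "required": ["config", "per_predator", "overlap", "breadth_difference"],
  "properties": {
    "config": {"type": "object"},
    "per_predator": {"type": "object"},
    "overlap": {
      "type": "object",
      "required": ["basis", "value"],
      "properties": {
        "basis": {"type": "string"},
        "value": {"type": ["number", "null"]},
        "rfo": {"type": ["number", "null"]},
        "biomass": {"type": ["number", "null"]}
      }
    },
    "breadth_difference": {
      "type": "object",
      "required": ["observed_diff", "p_value", "n_perm", "seed"],
      "properties": {
        "observed_diff": {"type": "number"},
        "p_value": {"type": "number"},
        "n_perm": {"type": "number"},
        "seed": {"type": ["number", "null"]}
      }
    },
    "warnings": {"type": "array"}
  }
}
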