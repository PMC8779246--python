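{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "bprsnet run report",
  "type": "object",
  "required": [
    "config",
    "n_subjects",
    "n_items",
    "possible_edges",
    "edge_count",
    "edge_fraction_pct",
    "selected_lambda",
    "top_edges",
    "centrality",
    "partition"
  ],
  "properties": {
    "config": {"type": "object"},
    "n_subjects": {"type": "integer", "minimum": 2},
    "n_items": {"type": "integer", "minimum": 2},
    "n_dropped_rows": {"type": "integer", "minimum": 0},
    "possible_edges": {"type": "integer", "minimum": 1},
    "edge_count": {"type": "integer", "minimum": 0},
    "edge_fraction_pct": {"type": "number", "minimum": 0, "maximum": 100},
    "selected_lambda": {"type": "number", "minimum": 0},
    "pd_adjusted": {"type": "boolean"},
    "top_edges": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["node_i", "node_j", "weight"],
        "properties": {
          "node_i": {"type": "string"},
          "node_j": {"type": "string"},
          "weight": {"type": "number"}
        }
      }
    },
    "centrality": {"type": "object"},
    "partition": {"type": "object"},
    "stability": {"type": "object"},
    "bootstrap": {"type": "object"},
    "permutation": {"type": "object"},
    "timings_sec": {"type": "object"},
    "versions": {"type": "object"}
  }
}
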