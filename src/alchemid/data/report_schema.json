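{
  "title": "alchemid pair run report",
  "type": "object",
  "required": [
    "pair_id",
    "k",
    "n_candidates",
    "n_failures",
    "parents_reconstructed",
    "candidates",
    "timings_s",
    "config"
  ],
  "properties": {
    "pair_id": {"type": "string"},
    "k": {"type": "integer"},
    "n_candidates": {"type": "integer"},
    "n_failures": {"type": "integer"},
    "parents_reconstructed": {"type": "boolean"},
    "candidates": {"type": "array", "items": {"type": "object"}},
    "timings_s": {"type": "object"},
    "config": {"type": "object"}
  }
}
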