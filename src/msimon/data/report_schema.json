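{
  "type": "object",
  "required_properties": {
    "config": {
      "type": "object",
      "required_properties": {
        "n_patients": {"type": "number"},
        "base_seed": {"type": "number"},
        "profile": {"type": "string"}
      }
    },
    "summary": {
      "type": "object",
      "required_properties": {
        "n_patients": {"type": "number"},
        "median_auroc": {"type": "number"},
        "mean_auroc": {"type": "number"},
        "profile": {"type": "string"}
      }
    },
    "patients": {
      "type": "array",
      "items": {
        "type": "object",
        "required_properties": {
          "patient": {"type": "string"},
          "auroc": {"type": "number"}
        }
      }
    }
  }
}
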