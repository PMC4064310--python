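{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "respanel panel report",
  "type": "object",
  "required": ["schema_version", "panels", "ranking"],
  "properties": {
    "schema_version": {"type": "string"},
    "panels": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": [
          "genes", "selection_model", "search_accuracy", "loocv_accuracy",
          "loocv_scores", "auc", "trajectory", "seed"
        ],
        "properties": {
          "genes": {"type": "array", "items": {"type": "string"}, "minItems": 1},
          "selection_model": {"enum": ["uniform", "f_prop", "min_f"]},
          "search_accuracy": {"type": "number", "minimum": 0, "maximum": 100},
          "loocv_accuracy": {"type": ["number", "null"], "minimum": 0, "maximum": 100},
          "loocv_scores": {"type": ["object", "null"]},
          "auc": {"type": ["number", "null"], "minimum": 0, "maximum": 1},
          "trajectory": {"type": "array"},
          "seed": {"type": ["integer", "null"]}
        }
      }
    },
    "ranking": {
      "type": ["object", "null"],
      "required": ["cv_threshold", "entries"],
      "properties": {
        "cv_threshold": {"type": "number"},
        "entries": {"type": "array"}
      }
    }
  }
}
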