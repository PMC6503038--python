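{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "brainage pipeline run manifest",
  "type": "object",
  "required": ["schema_version", "seed", "package_version", "stages"],
  "properties": {
    "schema_version": {"type": "integer", "const": 1},
    "seed": {"type": "integer"},
    "package_version": {"type": "string"},
    "stages": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "seed", "outputs", "rows"],
        "properties": {
          "name": {
            "enum": ["simulate", "train", "predict", "bag", "longitudinal", "associate"]
          },
          "seed": {"type": "integer"},
          "outputs": {"type": "object"},
          "rows": {"type": "object"},
          "wall_seconds": {"type": "number"}
        }
      }
    }
  }
}
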