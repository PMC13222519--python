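{
  "$comment": "Descriptive schema for the ncres AlphaFold3-style job specification (dialect ncres-af3, version 1). Field names follow the public AlphaFold3 input format where they are public; customComponents is an ncres extension referencing residue-definition CSV files. Enforced programmatically by ncres.export.validate_af3_job.",
  "type": "object",
  "required": ["dialect", "version", "name", "modelSeeds", "sequences", "customComponents"],
  "properties": {
    "dialect": {"type": "string", "const": "ncres-af3"},
    "version": {"type": "integer", "const": 1},
    "name": {"type": "string"},
    "modelSeeds": {"type": "array", "items": {"type": "integer"}},
    "sequences": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["protein"],
        "properties": {
          "protein": {
            "type": "object",
            "required": ["id", "sequence"],
            "properties": {
              "id": {"type": "string"},
              "sequence": {
                "type": "string",
                "$comment": "One-letter residue codes; X marks a position carrying a modification entry."
              },
              "modifications": {
                "type": "array",
                "items": {
                  "type": "object",
                  "required": ["ptmPosition", "ptmType"],
                  "properties": {
                    "ptmPosition": {"type": "integer", "minimum": 1, "$comment": "1-based; must not exceed the sequence length"},
                    "ptmType": {"type": "string", "pattern": "^[A-Z0-9]{1,3}$", "$comment": "standard code or a custom component_id resolvable via customComponents"}
                  }
                }
              }
            }
          }
        }
      }
    },
    "customComponents": {
      "type": "object",
      "$comment": "Exactly one of 'files' (list of CSV paths relative to the job file) or 'directory' (folder of CSVs).",
      "properties": {
        "files": {"type": "array", "items": {"type": "string"}},
        "directory": {"type": "string"}
      }
    }
  }
}
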