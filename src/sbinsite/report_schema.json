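{
  "type": "object",
  "required": [
    "schema_version",
    "parameters",
    "samples",
    "total_junction_reads",
    "total_unique_is",
    "chromosome_distribution",
    "tss_table",
    "logo",
    "abundance",
    "cis"
  ],
  "properties": {
    "schema_version": {"type": "string"},
    "parameters": {"type": "object"},
    "samples": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["sample_id", "n_is", "reads_mapped", "reads_discarded"],
        "properties": {
          "sample_id": {"type": "string"},
          "n_is": {"type": "integer"},
          "reads_mapped": {"type": "integer"},
          "reads_discarded": {"type": "object"}
        }
      }
    },
    "total_junction_reads": {"type": "integer"},
    "total_unique_is": {"type": "integer"},
    "chromosome_distribution": {
      "type": "object",
      "required": ["rows"],
      "properties": {"rows": {"type": "array"}}
    },
    "tss_table": {"type": "array"},
    "logo": {
      "type": "object",
      "required": ["offsets", "freq", "consensus", "n_sites"],
      "properties": {
        "offsets": {"type": "array"},
        "freq": {"type": "object"},
        "consensus": {"type": "string"},
        "n_sites": {"type": "integer"}
      }
    },
    "abundance": {
      "type": "object",
      "required": ["n_records", "labeled", "verdict"],
      "properties": {
        "n_records": {"type": "integer"},
        "labeled": {"type": "array"},
        "verdict": {"type": "string"}
      }
    },
    "cis": {
      "type": "object",
      "required": ["n_clusters", "p_global", "n_sim", "clusters"],
      "properties": {
        "n_clusters": {"type": "integer"},
        "p_global": {"type": "number"},
        "n_sim": {"type": "integer"},
        "clusters": {"type": "array"}
      }
    },
    "enrichment": {"type": "array"}
  }
}
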