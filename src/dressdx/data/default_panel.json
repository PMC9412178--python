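{
  "housekeeping": "YWHAZ",
  "genes": [
    {"id": "STAC", "direction": 1, "discovery_logfc": null, "importance": null, "source": "de_selected", "direction_source": "stated"},
    {"id": "GPR183", "direction": -1, "discovery_logfc": null, "importance": null, "source": "de_selected", "direction_source": "stated"},
    {"id": "CD40", "direction": 1, "discovery_logfc": null, "importance": null, "source": "de_selected", "direction_source": "unspecified"},
    {"id": "CISH", "direction": 1, "discovery_logfc": null, "importance": null, "source": "de_selected", "direction_source": "stated"},
    {"id": "CD4", "direction": -1, "discovery_logfc": null, "importance": null, "source": "de_selected", "direction_source": "stated"},
    {"id": "CCL8", "direction": 1, "discovery_logfc": null, "importance": null, "source": "de_selected", "direction_source": "stated"}
  ]
}
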