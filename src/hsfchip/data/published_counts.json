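{
  "beaf_contingency": {
    "induced": {"motif": 3, "external_binding": 3, "both": 2, "total": 11},
    "noninduced": {"motif": 69, "external_binding": 66, "both": 48, "total": 104}
  },
  "differential_expression": {
    "n_de_cells": 211,
    "n_de_larvae": 237,
    "n_de_both": 33
  },
  "binding": {
    "n_segments": 434,
    "n_unique_cytolocations": 265,
    "n_associated_genes": 471
  }
}
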