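{
  "_comment": [
    "Hand evaluation of the filter cascade on toy_quant.tsv, worked out",
    "before implementation.",
    "Stage 1 (min_peptides=2, biological samples only): F_PEP has max",
    "peptide count 1 over all biological samples -> removed. All others",
    "reach >= 2 in at least one biological sample.",
    "Stage 2 (control enrichment, raw areas, ratio 3, both conditions,",
    "inclusive >=; control mean 0 passes iff biological mean > 0):",
    "  PASS1: unt 110 vs 3*10=30 ok; str 200 vs 30 ok.",
    "  PASS2: unt 30 vs 30 ok (boundary); str 90 vs 90 ok (boundary).",
    "  PASS3: unt mean 110/3 with control mean 0 and bio > 0 ok; str mean",
    "         40 vs 3*5=15 ok.",
    "  F_CTRL_U: unt 20 vs 30 FAIL -> removed.",
    "  F_CTRL_S: unt 100 vs 30 ok; str 50 vs 60 FAIL -> removed.",
    "  F_PRES1: unt mean 30 > 0 with control 0 ok; str mean 80/3 > 0 ok.",
    "  F_PRES2: unt mean 5/3 > 0 ok; str mean 2 > 0 ok.",
    "Stage 3 (presence: area > 0 in >= 2 biological replicates of at least",
    "one condition):",
    "  PASS1 3+3, PASS2 3+3, PASS3 2+2 -> kept.",
    "  F_PRES1 1+1 -> removed. F_PRES2 1+1 -> removed."
  ],
  "survivors": ["PASS1", "PASS2", "PASS3"],
  "stages": [
    {"stage": "min_peptides", "proteins_in": 8, "proteins_out": 7,
     "removed": ["F_PEP"]},
    {"stage": "control_enrichment", "proteins_in": 7, "proteins_out": 5,
     "removed": ["F_CTRL_U", "F_CTRL_S"]},
    {"stage": "replicate_presence", "proteins_in": 5, "proteins_out": 3,
     "removed": ["F_PRES1", "F_PRES2"]}
  ]
}
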