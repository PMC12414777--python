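{
  "seed": 20250928,
  "files": [
    "carriers.csv",
    "variants.tsv",
    "genotypes.tsv",
    "constrained_cells.csv"
  ],
  "n_participants": 4856,
  "n_carriers": 86,
  "n_eligible": 76,
  "regenerate": "fh-triage simulate --what fixtures --out <dir>  (or fh_triage.build_table_fixtures(outdir))"
}
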