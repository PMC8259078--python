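{
 "reference_genes.fasta": "d4ec1e45dd25dd61f2ce9bf7eece5215b013a492dc6e7e4d352295f583071bf1",
 "per_gene_cds_sha256": {
  "YER148W": "328ee05e0a1231d648b1b981238a2dbc3ef30a6fe259298003c5ff2e47d7c281",
  "YEL021W": "8e60fa349bc0bca98487eff63ee5543ea2ad02d3948211debb144178ca35f935",
  "YAR015W": "a0c5e320f74e0a284fa4279828a715b659ff4c014393b13fffc9206881303807"
 }
}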