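{
  "study_records.tsv": "62a9bf6ab885b0f2b10316d70c4bd08a91900b3722196979981423dc2187191f",
  "focus_genes.tsv": "48afa11965262ad27306c83e30056898c859f527376a3787ac34f6489fa730d6",
  "agent_gene_matrix.tsv": "2f879042b195b35e70cd972d3abc3078ce2d126dd5800c5555e4a5e112457caa",
  "agent_papers.tsv": "6e6753c8181b54750ce1e97fc330581b89fa3ef6970c435bdd6243cfee3b7a44",
  "hub_tables.tsv": "e6173872e68bb413d8f410f9c28a1492b9dbfdd15ad7488996664f992c6bdab1"
}
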