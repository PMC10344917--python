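{
  "table1_table2_dc50.csv": "b0fe07dbdbbae207ec9c875c00f268122e21902f0b19283f8358836b77011660",
  "table3_brd4_bd1.csv": "469215ada7ce87593651493d3344669e2e43fac75d221d68f099aae8e35103f1",
  "table3_brd4_bd2.csv": "908bfed5fed2cc993dfefe5f42987eade6e015991faf3458fb180f7265b5f6de",
  "table3_smarca2.csv": "151cc6d6159807c0bbcb6747f9b58c0adfa3886a539f3762604bff3ba478a448",
  "vdw_radii.json": "ddb3cec2315c18471957fda4ebcd5f0473e6b57c9ba1ae4261597dba4bfb2419"
}
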