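{
  "table2_cluster1.csv": "da7b21f354652e8a31fa9af677787e1ec5bf5772cc649bc3341ba59d53e0fe59",
  "table4_summary.csv": "372a3019fe8c322401b3ac0a571d288694a6a61c0f50b53d5a0abdd176c73219"
}
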