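{
  "name": "NK_8gene",
  "cell_type": "NK",
  "genes": [
    "NCR1", "BTLA", "CD7", "CD160", "CD247", "GZMM", "KLRC1", "KLRC2"
  ]
}
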