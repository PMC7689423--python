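{
  "name": "DC_16gene",
  "cell_type": "DC",
  "genes": [
    "THBD", "AXL", "CX3CR1", "FOS", "GZMK", "IL18R1", "MEF2C", "PRF1",
    "SIGIRR", "SYK", "BAGE", "BIRC5", "CDK1", "CT45A", "PBK", "TTK"
  ]
}
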