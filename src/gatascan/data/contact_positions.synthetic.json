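{
  "description": "Synthetic stand-in for the 18 DNA-base-contacting alignment columns of the 55-column DBD layout, placed in the C2-C3 loop and proximal basic domain where cGATA1 base contacts lie.",
  "positions": [8, 9, 10, 11, 12, 13, 14, 15, 16, 25, 26, 27, 28, 29, 30, 31, 32, 33]
}
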