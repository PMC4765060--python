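BCL2A1
CASP3
CASP7
CDK1
IKBKB
MAP4K4
MCL1
NFKB2
TNFRSF1A
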