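ACIN1
BAX
KRAS
MAPK8
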