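IL12RB2
IL32
MMP9
NGF
OASL
TNFRSF12A
BMP4
CHP2
OSGIN1
PAK5
POMC
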