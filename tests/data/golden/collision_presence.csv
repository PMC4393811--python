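00A94D10B7,0.000000,60.000000
00F17A23C5,0.000000,60.000000
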