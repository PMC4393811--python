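10.000,TARGET_PLAYBACK,00F17A23C5
10.000,STILL_CAPTURE,00F17A23C5
200.000,SUPPRESSED_REFRACTORY,00F17A23C5
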