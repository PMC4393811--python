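30.000,TEST_PLAYBACK,00DEADBEEF
30.000,SUPPRESSED_CONTINUOUS,00DEADBEEF
346.000,TARGET_PLAYBACK,00F17A23C5
346.000,STILL_CAPTURE,00F17A23C5
347.000,SUPPRESSED_CONTINUOUS,00F17A23C5
616.000,TARGET_PLAYBACK,00F17A23C5
616.000,STILL_CAPTURE,00F17A23C5
616.000,SUPPRESSED_CONTINUOUS,00F17A23C5
1344.000,TARGET_PLAYBACK,00F17A23C5
1344.000,STILL_CAPTURE,00F17A23C5
1344.000,SUPPRESSED_CONTINUOUS,00F17A23C5
1569.000,TARGET_PLAYBACK,00F17A23C5
1569.000,STILL_CAPTURE,00F17A23C5
1570.000,SUPPRESSED_CONTINUOUS,00F17A23C5
1704.000,TARGET_PLAYBACK,00F17A23C5
1704.000,STILL_CAPTURE,00F17A23C5
1705.000,SUPPRESSED_CONTINUOUS,00F17A23C5
2240.000,TARGET_PLAYBACK,00F17A23C5
2240.000,STILL_CAPTURE,00F17A23C5
2241.000,SUPPRESSED_CONTINUOUS,00F17A23C5
2295.000,SUPPRESSED_REFRACTORY,00F17A23C5
2295.000,SUPPRESSED_CONTINUOUS,00F17A23C5
2438.000,TARGET_PLAYBACK,00F17A23C5
2438.000,STILL_CAPTURE,00F17A23C5
2439.000,SUPPRESSED_CONTINUOUS,00F17A23C5
2458.000,SUPPRESSED_REFRACTORY,00F17A23C5
2459.000,SUPPRESSED_CONTINUOUS,00F17A23C5
2948.000,TARGET_PLAYBACK,00F17A23C5
2948.000,STILL_CAPTURE,00F17A23C5
2949.000,SUPPRESSED_CONTINUOUS,00F17A23C5
3628.000,TEST_PLAYBACK,00DEADBEEF
3628.000,SUPPRESSED_CONTINUOUS,00DEADBEEF
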