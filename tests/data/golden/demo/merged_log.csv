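2014-06-10 06:00:00.000,30.000,TEST_PLAYBACK,00DEADBEEF
2014-06-10 06:00:00.000,30.000,SUPPRESSED_CONTINUOUS,00DEADBEEF
2014-06-10 06:05:16.000,346.000,TARGET_PLAYBACK,00F17A23C5
2014-06-10 06:05:16.000,346.000,STILL_CAPTURE,00F17A23C5
2014-06-10 06:05:17.000,347.000,SUPPRESSED_CONTINUOUS,00F17A23C5
2014-06-10 06:09:46.000,616.000,TARGET_PLAYBACK,00F17A23C5
2014-06-10 06:09:46.000,616.000,STILL_CAPTURE,00F17A23C5
2014-06-10 06:09:46.000,616.000,SUPPRESSED_CONTINUOUS,00F17A23C5
2014-06-10 06:21:54.000,1344.000,TARGET_PLAYBACK,00F17A23C5
2014-06-10 06:21:54.000,1344.000,STILL_CAPTURE,00F17A23C5
2014-06-10 06:21:54.000,1344.000,SUPPRESSED_CONTINUOUS,00F17A23C5
2014-06-10 06:25:39.000,1569.000,TARGET_PLAYBACK,00F17A23C5
2014-06-10 06:25:39.000,1569.000,STILL_CAPTURE,00F17A23C5
2014-06-10 06:25:40.000,1570.000,SUPPRESSED_CONTINUOUS,00F17A23C5
2014-06-10 06:27:54.000,1704.000,TARGET_PLAYBACK,00F17A23C5
2014-06-10 06:27:54.000,1704.000,STILL_CAPTURE,00F17A23C5
2014-06-10 06:27:55.000,1705.000,SUPPRESSED_CONTINUOUS,00F17A23C5
2014-06-10 06:36:50.000,2240.000,TARGET_PLAYBACK,00F17A23C5
2014-06-10 06:36:50.000,2240.000,STILL_CAPTURE,00F17A23C5
2014-06-10 06:36:51.000,2241.000,SUPPRESSED_CONTINUOUS,00F17A23C5
2014-06-10 06:37:45.000,2295.000,SUPPRESSED_REFRACTORY,00F17A23C5
2014-06-10 06:37:45.000,2295.000,SUPPRESSED_CONTINUOUS,00F17A23C5
2014-06-10 06:40:08.000,2438.000,TARGET_PLAYBACK,00F17A23C5
2014-06-10 06:40:08.000,2438.000,STILL_CAPTURE,00F17A23C5
2014-06-10 06:40:09.000,2439.000,SUPPRESSED_CONTINUOUS,00F17A23C5
2014-06-10 06:40:28.000,2458.000,SUPPRESSED_REFRACTORY,00F17A23C5
2014-06-10 06:40:29.000,2459.000,SUPPRESSED_CONTINUOUS,00F17A23C5
2014-06-10 06:48:38.000,2948.000,TARGET_PLAYBACK,00F17A23C5
2014-06-10 06:48:38.000,2948.000,STILL_CAPTURE,00F17A23C5
2014-06-10 06:48:39.000,2949.000,SUPPRESSED_CONTINUOUS,00F17A23C5
2014-06-10 06:59:58.000,3628.000,TEST_PLAYBACK,00DEADBEEF
2014-06-10 06:59:58.000,3628.000,SUPPRESSED_CONTINUOUS,00DEADBEEF
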