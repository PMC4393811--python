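00A94D10B7,455.462103,472.078306
00A94D10B7,1121.665490,1124.902255
00A94D10B7,1296.593206,1314.005256
00A94D10B7,1784.483590,1787.862457
00A94D10B7,2208.615591,2210.437960
00A94D10B7,2934.272871,2938.806771
00A94D10B7,3450.730731,3463.282571
00DEADBEEF,0.000000,2.000000
00DEADBEEF,3598.000000,3600.000000
00F17A23C5,316.211422,317.269489
00F17A23C5,586.118073,588.057644
00F17A23C5,1311.490241,1316.624603
00F17A23C5,1539.524088,1541.609444
00F17A23C5,1674.471944,1676.237208
00F17A23C5,1677.307761,1679.768209
00F17A23C5,2208.615591,2211.946088
00F17A23C5,2264.982193,2266.217545
00F17A23C5,2408.612908,2415.585330
00F17A23C5,2428.611524,2431.278942
00F17A23C5,2918.620810,2921.450004
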