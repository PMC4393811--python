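nest_id,duration_hr,visits_per_hr,playbacks_per_hr,seed,config_hash
demo,1.0000,10.000000,8.000000,2014,7b7ba0feff20313e
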