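{
  "artifacts": {
    "controller_log.csv": "475c3021352d5c3e75f5d95d83fea1427f9b857c835db831677eb2956c926838",
    "merged_log.csv": "ab689c17120cb7690706afa0398c795508a50bd36272a57ffd0f2ea0c9bf51a4",
    "presence.csv": "7a623a772a4ff80f71fcff4981b1465000a82dc59e1a376aa24f7c44cd82b609",
    "rfid_log.csv": "c7acda4f1564842ad30cdc4c006e7baabe4c595bcc815fd2153f9ac0d169e598",
    "summary.csv": "392e4c69495c68233f70983f0a7b7d4a50d9b42adc7469f44e3ea2a6522f2814"
  },
  "config": {
    "controller": {
      "actuation_latency_s": 0.0,
      "capture_still": true,
      "episode_gap_s": 1.0,
      "multi_tag_withhold_s": null,
      "per_tag_refractory": false,
      "refractory_s": 120.0,
      "stimulus_ref": "stimulus.wav",
      "target_tags": [
        "00F17A23C5"
      ],
      "test_stimulus_ref": "test.wav",
      "test_tags": [
        "00DEADBEEF"
      ]
    },
    "controller_startup_lead_s": 30.0,
    "deployment_start": "2014-06-10 06:00:00",
    "duty": {
      "min_overlap_s": 0.1,
      "pause_s": 0.2,
      "read_window_s": 0.3
    },
    "nest_id": "demo",
    "reader_id": {
      "value": "AB12"
    },
    "scenario": {
      "duration_s": 3600.0,
      "individuals": [
        {
          "params": {
            "dwell_mean_s": 5.0,
            "dwell_min_s": 1.0,
            "min_gap_s": 0.0,
            "visit_rate_per_hr": 8.96
          },
          "role": "target",
          "tag_id": {
            "value": "00F17A23C5"
          }
        },
        {
          "params": {
            "dwell_mean_s": 5.0,
            "dwell_min_s": 1.0,
            "min_gap_s": 0.0,
            "visit_rate_per_hr": 8.96
          },
          "role": "nontarget",
          "tag_id": {
            "value": "00A94D10B7"
          }
        },
        {
          "params": null,
          "role": "test",
          "tag_id": {
            "value": "00DEADBEEF"
          }
        }
      ],
      "overlap_prob": 0.05,
      "seed": 0
    },
    "seed": 2014
  },
  "config_hash": "7b7ba0feff20313e",
  "seed": 2014
}
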