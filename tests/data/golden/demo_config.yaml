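# Demo deployment: one focal (target) female, one non-target male, one test tag.
nest_id: demo
seed: 0
deployment_start: "2014-06-10 06:00:00"
reader_id: "AB12"
duty_cycle: {read_window_s: 0.3, pause_s: 0.2, min_overlap_s: 0.1}
controller:
  refractory_s: 120.0
  episode_gap_s: 1.0
  capture_still: true
scenario:
  duration_s: 3600
  overlap_prob: 0.05
  individuals:
    - {tag: "00F17A23C5", role: target, visit_rate_per_hr: 8.96}
    - {tag: "00A94D10B7", role: nontarget, visit_rate_per_hr: 8.96}
    - {tag: "00DEADBEEF", role: test}
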