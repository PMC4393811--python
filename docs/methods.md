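# Methods

This note documents the model behind `pitstop`, the defaults it ships with,
and the reasoning behind choices the underlying system leaves open.

## The system being modelled

A passive RFID reader with a small antenna at a nestbox entrance detects
EM4102 PIT tags (40-bit identities, rendered as 10 hex characters) on
tagged birds. The reader energizes its antenna on a duty cycle — a 0.3 s
read window followed by a 0.2 s pause — and appends one line per detection
(tag ID, date-time to the second) to its log. A single-board computer
receives each detection over a serial line and runs the playback
controller: when the *target* individual's tag is detected, it plays an
audio stimulus (and optionally captures a still image); a *test* tag lets
the experimenter verify the rig in the field. The computer has no
battery-backed real-time clock, so its own event log counts elapsed seconds
since startup.

`pitstop` reproduces this chain in software: ground-truth presence
intervals → duty-cycled detection stream → controller decisions → dual-log
clock synchronization → rate analytics. All hardware concerns (power,
antenna physics, audio output, camera) are out of scope; actuators are
callbacks that report success or failure.

## Visit process (synthetic ground truth)

Each individual's visits arrive as a homogeneous Poisson process at
`visit_rate_per_hr`; each visit has dwell `dwell_min_s + Exp(dwell_mean_s −
dwell_min_s)`. An arrival that falls during the previous visit (or within
`min_gap_s` after it) is discarded: a bird already at the entrance cannot
*re*-arrive, so per-tag intervals are always disjoint. Defaults:

| parameter            | default | why |
|----------------------|---------|-----|
| `visit_rate_per_hr`  | 8.96 (focal female) | the mean provisioning-visit rate the deployments measured |
| male rate            | 8.96    | no male rate was reported; set equal to the female's |
| `dwell_mean_s` / `dwell_min_s` | 5 / 1 s | entrance dwell times are unreported; these straddle the 0.5 s read cycle so detection logic is exercised, and 1 s ≥ the 0.4 s guaranteed-detection dwell |
| `min_gap_s`          | 0       | Poisson is the minimal assumption; raising the gap disperses visits (real provisioning visits are more regular than Poisson, which is why the field playback rate nearly equalled the visit rate despite the refractory) |
| `overlap_prob`       | 0.05    | occasional male/female co-presence at the entrance is plausible but was only noted as a possibility; 5 % exercises the collision rule without dominating the statistics |
| deployment duration  | 6 h     | the field session length |

Test-tag individuals are deterministic: one 2 s swipe at deployment start
and one at the end, mirroring the field verification protocol and providing
the clock-sync anchors.

What the generator does **not** emulate: diurnal rhythm, weather, begging
feedback on provisioning, sex differences, or behavioural responses to the
playback itself. Tests passing against this generator therefore validate
the *instrument* (detection, triggering, logging, synchronization,
bookkeeping), not any biological hypothesis about provisioning.

## Reader model

Read windows start at t = 0, k·(0.3+0.2) s apart. Within a window, a tag is
readable if its presence overlaps the window by at least `min_overlap_s`
(default 0.1 s) — the minimum energized time needed to decode an identity,
a firmware property not published, hence a single conservative tunable.
Exactly one readable tag → one record, timestamped `floor(window start)`
(the log records whole seconds). Two or more readable tags → no record at
all: the single-tag reader cannot store anything while multiple tags are in
range. Collision is evaluated per window, the device's operating
resolution. Read success is deterministic given overlap; no failure rate is
published, so none is modelled (noise can be layered on the detection
stream if needed).

Closed form used by the tests: the minimal solo dwell that guarantees a
read at *any* arrival phase is `pause_s + 2·min_overlap_s` (0.4 s at
defaults) — the worst phase wastes just under `min_overlap_s` at the end of
one window and must then survive the pause and cover `min_overlap_s` of the
next. An exhaustive 1 ms phase sweep confirms both the guarantee and its
tightness (10 ms less admits a blind phase).

Numerical choice: window-overlap comparisons carry a 1 ns slack so the
exact boundary case (overlap equal to `min_overlap_s`) is inclusive under
IEEE arithmetic; without it, phases where `0.3 − 0.2 ≠ 0.1` in floating
point would spuriously miss.

## Controller semantics

A *detection episode* is a maximal run of one tag's reads with inter-read
gaps ≤ `episode_gap_s` (default 1.0 s — two full read cycles, since a
continuously present tag is legitimately read only once per 0.5 s cycle and
may miss one window to a transient collision). Per new episode of a target
tag, in priority order:

1. **refractory** — if a playback occurred within the last `refractory_s`
   (field value 120 s), log `SUPPRESSED_REFRACTORY`. The dead time is
   *non-extending* (anchored at the last emitted playback; suppressed
   episodes do not refresh it) and global across target tags — with a
   single focal target the per-tag/global distinction is unobservable, so
   the simpler global rule is the default and a per-tag flag is provided.
2. **multi-tag withholding** (off by default) — if a *different* tag was
   read within `multi_tag_withhold_s`, log `WITHHELD_MULTITAG`. This
   implements the defence against near-coincident arrivals, described for
   the rig only as an option.
3. otherwise fire the playback actuator, log `TARGET_PLAYBACK`, and (by
   default) capture a still (`STILL_CAPTURE`). Still capture is tied to
   playback-triggering detections; whether the field rig photographed
   suppressed detections too is unstated.

Test-tag episodes always fire the test playback and neither consult nor
start the refractory and take no still: their purpose is field
verification, so the least-interfering behaviour is chosen. Reads that
continue an episode log nothing except a single `SUPPRESSED_CONTINUOUS`
marker on the episode's second read. Tags that are neither target nor test
produce no events but do feed the multi-tag rule. An actuator failure is
logged (`ACTUATOR_ERROR`) and processing continues; a failed playback does
not start a refractory. The `SUPPRESSED_*`/`WITHHELD_*`/`ACTUATOR_ERROR`
kinds are bookkeeping additions — the field log recorded only target and
test playbacks — and `PAPER_FAITHFUL_KINDS` filters a log down to that
view.

The field rig triggered its actuator in under a second; in simulation the
latency is an explicit contract value (`actuation_latency_s`, default 0,
validated < 1 s) applied uniformly to the logged times of all events
produced by one read, which keeps the log's elapsed clock monotone even
when two reads share a quantized second.

## Clock synchronization

The first `TEST_PLAYBACK` in the controller log is paired with the first
test-tag detection in the reader log; the constant offset between them maps
every elapsed time to real time. Zero relative drift is assumed — adequate
over 6 h, and consistent with anchoring on a single event. A two-anchor
mode (first–first and last–last pairing, linear mapping) absorbs a constant
clock-rate error for longer runs; it is off by default. If either log lacks
a test-tag event the logs are declared unanchorable — an explicit error,
not a guess. Behaviour after a mid-deployment controller restart (elapsed
clock reset) is undefined and flagged as such.

With both simulated clocks quantized to 1 s, reconstructed playback times
land within 1.5 s of the ground-truth visit start (1 s quantization plus up
to one read cycle of detection latency); the end-to-end tests assert this
bound event by event.

## Analytics

Per deployment: visits/hr = focal-tag episodes (same gap rule as the
controller) per hour from the reader log; playbacks/hr = `TARGET_PLAYBACK`
events per hour from the controller log. Across nests: mean, SE (sample
SD/√n — the conventional reading of "± SE"), and Pearson r (the
conventional reading of an unqualified "r"). The per-nest table loader
sniffs header names ("visit", "playback", nest/id/box/site) so tables with
descriptive column titles load without configuration.

The refractory acting on Poisson episode arrivals is classical
non-extending dead time: accepted rate λ/(1 + λT). At λ = 8.96/hr and
T = 120 s this gives 6.90/hr. The acceptance checks run the *full* chain
(visit simulation → reader → controller) for 3000 simulated hours and
require agreement with the closed form within 2 %. For that run the dwell
is a short constant (1.2 s — above the 0.4 s detection guarantee, far below
the ~400 s mean inter-visit gap) so that episode starts remain Poisson to a
very good approximation; with the default 5 s mean dwell the episode-start
process is slightly thinned (≈1 %) and the comparison would conflate dwell
effects with dead-time behaviour. 3000 hours puts the Monte-Carlo standard
error near 0.5 %, comfortably inside the 2 % band, while running in about a
second.

The simulated 37-nest campaign (6 h per nest, independent sub-seeds) yields
mean visit rates near 8.7/hr — the 8.96/hr arrival rate minus dwell-merge
and collision losses, which are part of the modelled detection process —
and playback rates near the dead-time prediction, with visit and playback
rates strongly correlated across nests. Because the generator's visits are
Poisson, the simulated playback deficit is *larger* than the field study's
(which observed playbacks ≈ visits, implying dispersed real visits); the
campaign is a self-consistency exercise for the pipeline, not a re-estimate
of the field numbers.

## Reproducibility choices

One run seed feeds a SHA-256-derived sub-seed per purpose (visit
simulation, each nest of a campaign), each spawning per-individual NumPy
generators through `SeedSequence`; identical config + seed reproduces every
artifact byte for byte. Log dialects are headerless by design, so
provenance (seed, config hash, per-artifact SHA-256) lives in each run's
`manifest.json`. Sub-seeds stay below 2³¹.

## Known limitations

* Serial byte protocols and true baud rates of the two reader generations
  are not published; the generation profiles are placeholders selected by
  the presence of a 4-character reader ID, and the log dialect is this
  package's canonical CSV, not any particular firmware's.
* Read success is deterministic; real antennas have orientation- and
  range-dependent failure.
* The controller consumes the reader's 1 s-quantized records; the physical
  serial stream has sub-second arrival times the simulation does not carry.
* Dwell-time and overlap defaults are plausible stand-ins, not estimates
  from data.
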