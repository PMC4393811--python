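"""Run configuration, YAML loading, and reproducible end-to-end runs.

One seed drives everything: a NumPy SeedSequence spawned from the run seed
feeds the visit simulator, so identical (config, seed) pairs produce
byte-identical artifact bundles.  A run writes five artifacts to the output
directory:

* ``presence.csv``   — ground-truth presence intervals (tag, start_s, end_s)
* ``rfid_log.csv``   — the reader's detection log (canonical dialect)
* ``controller_log.csv`` — the controller's elapsed-time event log
* ``merged_log.csv`` — controller events with reconstructed real times
* ``summary.csv``    — the per-deployment rate summary

plus ``manifest.json`` holding the seed, a config hash, and a sha256 per
artifact, so a re-run can be verified bit-for-bit.  The log dialects are
headerless, so provenance metadata lives in the manifest rather than in
per-file header comments.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from . import analytics, clock_sync, controller, reader_sim, tag_protocol, visit_sim
from .controller import ControllerConfig
from .reader_sim import DutyCycle
from .tag_protocol import ReaderID, TagID, infer_generation
from .visit_sim import Individual, Role, SiteScenario, VisitProcessParams

__all__ = [
    "RunConfig",
    "RunResult",
    "load_run_config",
    "load_scenario",
    "run_end_to_end",
    "generate_fixtures",
    "derive_seed",
]

DEFAULT_DEPLOYMENT_START = datetime(2014, 6, 10, 6, 0, 0)


@dataclass(frozen=True)
class RunConfig:
    """Everything an end-to-end simulated deployment needs."""

    scenario: SiteScenario
    controller: ControllerConfig
    duty: DutyCycle = DutyCycle()
    seed: int = 0
    deployment_start: datetime = DEFAULT_DEPLOYMENT_START
    # the Pi is booted and the script launched before the reader goes live,
    # so the elapsed clock leads the deployment by a bit
    controller_startup_lead_s: float = 30.0
    reader_id: Optional[ReaderID] = None
    nest_id: str = "nest"

    def __post_init__(self) -> None:
        if self.controller_startup_lead_s < 0:
            raise ValueError("controller_startup_lead_s must be >= 0")
        if self.deployment_start.microsecond != 0:
            raise ValueError("deployment_start must be a whole second")


@dataclass(frozen=True)
class RunResult:
    presence: dict[TagID, list]
    reads: list
    events: list
    aligned: list
    summary: analytics.DeploymentSummary
    out_dir: Optional[Path] = None
    manifest: Optional[dict] = None


def derive_seed(seed: int, label: str) -> int:
    """A stable sub-seed (< 2**31) for a named purpose under one run seed."""
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _config_dict(config: RunConfig) -> dict:
    def default(o: Any):
        if isinstance(o, (TagID, ReaderID)):
            return o.value
        if isinstance(o, frozenset):
            return sorted(x.value if isinstance(x, TagID) else x for x in o)
        if isinstance(o, datetime):
            return o.isoformat(sep=" ")
        if isinstance(o, Role):
            return o.value
        raise TypeError(type(o))

    raw = dataclasses.asdict(config)
    return json.loads(json.dumps(raw, default=default, sort_keys=True))


def config_hash(config: RunConfig) -> str:
    canon = json.dumps(_config_dict(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_end_to_end(config: RunConfig, out_dir: Optional[Path] = None) -> RunResult:
    """Simulate one deployment through the whole chain and (optionally) write artifacts.

    Deterministic: the same (config, out_dir-independent) inputs yield
    byte-identical artifacts.  The scenario's own seed field is overridden
    by a sub-seed derived from ``config.seed``.
    """
    scenario = dataclasses.replace(
        config.scenario, seed=derive_seed(config.seed, "visits")
    )
    presence = visit_sim.simulate_site(scenario)
    reads = reader_sim.simulate_reads(
        presence,
        config.duty,
        deployment_start=config.deployment_start,
        reader_id=config.reader_id,
    )
    startup = config.deployment_start - timedelta(
        seconds=config.controller_startup_lead_s
    )
    events = controller.process_stream(
        reads, config.controller, startup_time=startup
    )
    test_tags = config.controller.test_tags
    aligned: list[clock_sync.AlignedEvent] = []
    if test_tags:
        try:
            anchor = clock_sync.find_anchor(reads, events, test_tags)
            aligned = clock_sync.align(events, anchor)
        except clock_sync.UnanchorableError:
            aligned = []
    duration_hr = scenario.duration_s / 3600.0
    focal = _focal_tag(scenario, config.controller)
    summary = analytics.summarize_deployment(
        reads,
        events,
        focal,
        duration_hr,
        nest_id=config.nest_id,
        episode_gap_s=config.controller.episode_gap_s,
    )

    manifest = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        artifacts = {
            "presence.csv": visit_sim.write_presence_csv(presence),
            "rfid_log.csv": tag_protocol.write_rfid_log(reads),
            "controller_log.csv": controller.write_controller_log(events),
            "merged_log.csv": clock_sync.write_merged_log(aligned),
            "summary.csv": _summary_csv(summary, config),
        }
        shas = {}
        for name, text in artifacts.items():
            (out_dir / name).write_text(text, encoding="utf-8")
            shas[name] = hashlib.sha256(text.encode()).hexdigest()
        manifest = {
            "seed": config.seed,
            "config_hash": config_hash(config),
            "config": _config_dict(config),
            "artifacts": shas,
        }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    return RunResult(presence, reads, events, aligned, summary, out_dir, manifest)


def _focal_tag(scenario: SiteScenario, cfg: ControllerConfig) -> TagID:
    for ind in scenario.individuals:
        if ind.role is Role.TARGET and ind.tag_id in cfg.target_tags:
            return ind.tag_id
    for ind in scenario.individuals:
        if ind.role is Role.TARGET:
            return ind.tag_id
    raise ValueError("scenario has no target individual")


def _summary_csv(summary: analytics.DeploymentSummary, config: RunConfig) -> str:
    header = "nest_id,duration_hr,visits_per_hr,playbacks_per_hr,seed,config_hash\n"
    row = (
        f"{summary.nest_id},{summary.duration_hr:.4f},"
        f"{summary.visits_per_hr:.6f},{summary.playbacks_per_hr:.6f},"
        f"{config.seed},{config_hash(config)}\n"
    )
    return header + row


# ---------------------------------------------------------------------------
# YAML loading


def _parse_individual(entry: Mapping[str, Any]) -> Individual:
    role = Role(str(entry["role"]).lower())
    tag = TagID(str(entry["tag"]))
    if role is Role.TEST:
        return Individual(tag, role)
    params = VisitProcessParams(
        visit_rate_per_hr=float(entry["visit_rate_per_hr"]),
        dwell_mean_s=float(entry.get("dwell_mean_s", 5.0)),
        dwell_min_s=float(entry.get("dwell_min_s", 1.0)),
        min_gap_s=float(entry.get("min_gap_s", 0.0)),
    )
    return Individual(tag, role, params)


def load_scenario(data: Mapping[str, Any]) -> SiteScenario:
    """Build a SiteScenario from a parsed YAML/dict section."""
    individuals = tuple(_parse_individual(e) for e in data.get("individuals", ()))
    return SiteScenario(
        duration_s=float(data.get("duration_s", 6 * 3600.0)),
        individuals=individuals,
        overlap_prob=float(data.get("overlap_prob", 0.05)),
        seed=int(data.get("seed", 0)),
    )


def _parse_controller(data: Mapping[str, Any]) -> ControllerConfig:
    withhold = data.get("multi_tag_withhold_s")
    return ControllerConfig(
        target_tags=frozenset(TagID(str(t)) for t in data.get("target_tags", ())),
        test_tags=frozenset(TagID(str(t)) for t in data.get("test_tags", ())),
        refractory_s=float(data.get("refractory_s", 120.0)),
        episode_gap_s=float(data.get("episode_gap_s", 1.0)),
        multi_tag_withhold_s=None if withhold is None else float(withhold),
        capture_still=bool(data.get("capture_still", True)),
        actuation_latency_s=float(data.get("actuation_latency_s", 0.0)),
        per_tag_refractory=bool(data.get("per_tag_refractory", False)),
    )


def _parse_duty(data: Mapping[str, Any]) -> DutyCycle:
    return DutyCycle(
        read_window_s=float(data.get("read_window_s", 0.3)),
        pause_s=float(data.get("pause_s", 0.2)),
        min_overlap_s=float(data.get("min_overlap_s", 0.1)),
    )


def load_run_config(path: Path | str, seed: Optional[int] = None) -> RunConfig:
    """Load a full run configuration from YAML, validating before any simulation.

    ``seed`` overrides the file's seed (the CLI's --seed flag).  A
    ``reader_id`` entry, when present, must be a valid 4-character code; its
    presence selects the Generation-2 serial profile, its absence Generation 1
    (the profile is informational in simulation).
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    scenario = load_scenario(data.get("scenario", {}))
    ctrl_data = dict(data.get("controller", {}))
    if not ctrl_data.get("target_tags"):
        ctrl_data["target_tags"] = [
            ind.tag_id.value
            for ind in scenario.individuals
            if ind.role is Role.TARGET
        ]
    if not ctrl_data.get("test_tags"):
        ctrl_data["test_tags"] = [
            ind.tag_id.value for ind in scenario.individuals if ind.role is Role.TEST
        ]
    reader_token = data.get("reader_id")
    generation = infer_generation(reader_token)  # validates the token
    start_text = data.get("deployment_start")
    start = (
        datetime.fromisoformat(str(start_text))
        if start_text is not None
        else DEFAULT_DEPLOYMENT_START
    )
    return RunConfig(
        scenario=scenario,
        controller=_parse_controller(ctrl_data),
        duty=_parse_duty(data.get("duty_cycle", {})),
        seed=int(seed if seed is not None else data.get("seed", 0)),
        deployment_start=start,
        controller_startup_lead_s=float(data.get("controller_startup_lead_s", 30.0)),
        reader_id=(
            ReaderID(str(reader_token)) if generation.name == "GEN2" else None
        ),
        nest_id=str(data.get("nest_id", "nest")),
    )


DEMO_CONFIG_YAML = """\
# Demo deployment: one focal (target) female, one non-target male, one test tag.
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
  duration_s: 21600
  overlap_prob: 0.05
  individuals:
    - {tag: "00F17A23C5", role: target, visit_rate_per_hr: 8.96}
    - {tag: "00A94D10B7", role: nontarget, visit_rate_per_hr: 8.96}
    - {tag: "00DEADBEEF", role: test}
"""


# ---------------------------------------------------------------------------
# Whole-chain experiments


def simulate_dead_time_rate(
    lambda_per_hr: float = 8.96,
    refractory_s: float = 120.0,
    hours: float = 1000.0,
    seed: int = 0,
    dwell_s: float = 1.2,
) -> float:
    """Accepted-playback rate of Poisson visit episodes under the refractory.

    Runs the *full* chain — visit simulation, duty-cycled reader, controller —
    over one long deployment and returns TARGET_PLAYBACK events per hour.
    A short constant dwell (default 1.2 s: long enough to guarantee reads,
    tiny against the ~400 s mean inter-visit gap) keeps episode starts
    Poisson, so the result is comparable to the renewal-theory closed form
    ``lambda / (1 + lambda * T)``.
    """
    tag = visit_sim.FEMALE_TAG
    scenario = SiteScenario(
        duration_s=hours * 3600.0,
        individuals=(
            Individual(
                tag,
                Role.TARGET,
                VisitProcessParams(
                    visit_rate_per_hr=lambda_per_hr,
                    dwell_mean_s=dwell_s,
                    dwell_min_s=dwell_s,
                ),
            ),
        ),
        overlap_prob=0.0,
        seed=derive_seed(seed, "dead-time"),
    )
    presence = visit_sim.simulate_site(scenario)
    reads = reader_sim.simulate_reads(presence, DutyCycle(), DEFAULT_DEPLOYMENT_START)
    cfg = ControllerConfig(
        target_tags=frozenset({tag}), refractory_s=refractory_s, capture_still=False
    )
    events = controller.process_stream(reads, cfg)
    n_playbacks = sum(
        1 for e in events if e.kind is controller.EventKind.TARGET_PLAYBACK
    )
    return n_playbacks / hours


def simulate_campaign(
    n_nests: int = 37,
    seed: int = 0,
    scenario: Optional[SiteScenario] = None,
    controller_config: Optional[ControllerConfig] = None,
) -> list[analytics.DeploymentSummary]:
    """Simulate a multi-nest field campaign; one summary per nest.

    Every nest runs the default single-focal-female deployment (6 h, 120 s
    refractory) under an independent sub-seed, mirroring how the field study
    deployed one rig per nest.
    """
    if scenario is None:
        scenario = visit_sim.DEFAULT_SCENARIO
    if controller_config is None:
        controller_config = ControllerConfig(
            target_tags=frozenset(
                ind.tag_id for ind in scenario.individuals if ind.role is Role.TARGET
            ),
            test_tags=frozenset(
                ind.tag_id for ind in scenario.individuals if ind.role is Role.TEST
            ),
        )
    summaries = []
    for i in range(n_nests):
        cfg = RunConfig(
            scenario=scenario,
            controller=controller_config,
            seed=derive_seed(seed, f"nest-{i}"),
            nest_id=f"nest{i + 1:02d}",
        )
        summaries.append(run_end_to_end(cfg).summary)
    return summaries


# ---------------------------------------------------------------------------
# Fixture generation


def generate_fixtures(out_dir: Path | str, seed: int = 2014) -> dict[str, Path]:
    """Emit the deterministic fixture set used by the test suite.

    * ``demo/`` — a compact (1 h) end-to-end artifact bundle;
    * ``collision_presence.csv`` + ``collision_rfid_log.csv`` — two tags
      fully co-present, hence an *empty* reader log (the collision rule);
    * ``unanchorable_controller_log.csv`` — a controller log with no
      TEST_PLAYBACK, for the clock-sync error path;
    * ``demo_config.yaml`` — the YAML the demo bundle was produced from.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    cfg_path = out_dir / "demo_config.yaml"
    demo_yaml = DEMO_CONFIG_YAML.replace("duration_s: 21600", "duration_s: 3600")
    cfg_path.write_text(demo_yaml, encoding="utf-8")
    paths["demo_config"] = cfg_path

    config = load_run_config(cfg_path, seed=seed)
    run_end_to_end(config, out_dir / "demo")
    paths["demo"] = out_dir / "demo"

    tag_a = TagID("00F17A23C5")
    tag_b = TagID("00A94D10B7")
    collision_presence = {
        tag_a: [visit_sim.PresenceInterval(tag_a, 0.0, 60.0)],
        tag_b: [visit_sim.PresenceInterval(tag_b, 0.0, 60.0)],
    }
    (out_dir / "collision_presence.csv").write_text(
        visit_sim.write_presence_csv(collision_presence), encoding="utf-8"
    )
    collision_reads = reader_sim.simulate_reads(collision_presence)
    (out_dir / "collision_rfid_log.csv").write_text(
        tag_protocol.write_rfid_log(collision_reads), encoding="utf-8"
    )
    paths["collision_presence"] = out_dir / "collision_presence.csv"
    paths["collision_rfid_log"] = out_dir / "collision_rfid_log.csv"

    unanchorable = [
        controller.ActionEvent(10.0, controller.EventKind.TARGET_PLAYBACK, tag_a),
        controller.ActionEvent(10.0, controller.EventKind.STILL_CAPTURE, tag_a),
        controller.ActionEvent(200.0, controller.EventKind.SUPPRESSED_REFRACTORY, tag_a),
    ]
    (out_dir / "unanchorable_controller_log.csv").write_text(
        controller.write_controller_log(unanchorable), encoding="utf-8"
    )
    paths["unanchorable_controller_log"] = out_dir / "unanchorable_controller_log.csv"
    return paths
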