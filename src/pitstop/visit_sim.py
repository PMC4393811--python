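"""Synthetic ground truth: when is each tagged bird within antenna range?

Emulates nest-entrance presence at a nestbox antenna during a deployment.
Visits of one individual arrive as a homogeneous Poisson process; each visit
gets a dwell drawn from a shifted exponential.  An arrival that falls while
the bird is (per the simulation) still at the entrance — or closer than
``min_gap_s`` after it left — is dropped, which keeps per-tag intervals
disjoint and mirrors the fact that an ongoing presence cannot re-begin.

A site scenario composes independent per-individual processes: one focal
(target) female whose entries trigger the playback, a non-target male, and a
test tag.  The test tag mirrors the field protocol: the experimenter swipes
it past the antenna once right after deployment and once at pickup, giving
the clock-sync anchors.  To exercise the reader's tag-collision rule, each
male visit is, with probability ``overlap_prob``, rescheduled to coincide
with a uniformly chosen female visit.

Only the statistical structure needed to test the controller is modelled:
no diurnal rhythm, no sex difference in provisioning, no weather.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .tag_protocol import TagID

__all__ = [
    "PresenceInterval",
    "VisitProcessParams",
    "Role",
    "Individual",
    "SiteScenario",
    "DEFAULT_SCENARIO",
    "simulate_visits",
    "simulate_site",
    "write_presence_csv",
    "parse_presence_csv",
]

#: Dwell of each experimenter test-tag swipe, seconds. Comfortably above the
#: 0.4 s guaranteed-detection dwell of the default duty cycle.
TEST_SWIPE_DWELL_S = 2.0


@dataclass(frozen=True, order=True)
class PresenceInterval:
    """Ground truth: ``tag_id`` is within reading range during [start_s, end_s)."""

    tag_id: TagID
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.start_s < self.end_s):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start_s}, {self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class VisitProcessParams:
    """Parameters of one individual's visit process.

    visit_rate_per_hr
        Poisson arrival rate of visits.  Zero is legal and yields no visits.
    dwell_mean_s / dwell_min_s
        Dwell ~ dwell_min_s + Exp(dwell_mean_s - dwell_min_s); equal values
        give a constant dwell.  Field dwell distributions at the entrance are
        unreported, so these are tunable with placeholder defaults.
    min_gap_s
        Minimum gap enforced between consecutive visits of the same tag.
    """

    visit_rate_per_hr: float
    dwell_mean_s: float = 5.0
    dwell_min_s: float = 1.0
    min_gap_s: float = 0.0

    def __post_init__(self) -> None:
        if self.visit_rate_per_hr < 0:
            raise ValueError(f"visit_rate_per_hr must be >= 0, got {self.visit_rate_per_hr}")
        if self.dwell_min_s < 0:
            raise ValueError(f"dwell_min_s must be >= 0, got {self.dwell_min_s}")
        if self.dwell_mean_s < self.dwell_min_s or self.dwell_mean_s <= 0:
            raise ValueError(
                f"dwell_mean_s must be positive and >= dwell_min_s "
                f"(got mean {self.dwell_mean_s}, min {self.dwell_min_s})"
            )
        if self.min_gap_s < 0:
            raise ValueError(f"min_gap_s must be >= 0, got {self.min_gap_s}")


class Role(str, Enum):
    TARGET = "target"
    NONTARGET = "nontarget"
    TEST = "test"


@dataclass(frozen=True)
class Individual:
    tag_id: TagID
    role: Role
    params: Optional[VisitProcessParams] = None

    def __post_init__(self) -> None:
        if self.role is not Role.TEST and self.params is None:
            raise ValueError(f"{self.role.value} individual {self.tag_id} needs visit params")


@dataclass(frozen=True)
class SiteScenario:
    """One nest's deployment: who is tagged, for how long, with what seed."""

    duration_s: float = 6 * 3600.0
    individuals: tuple[Individual, ...] = ()
    overlap_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if not (0.0 <= self.overlap_prob <= 1.0):
            raise ValueError(f"overlap_prob must be in [0, 1], got {self.overlap_prob}")
        tags = [ind.tag_id for ind in self.individuals]
        if len(set(tags)) != len(tags):
            raise ValueError(f"duplicate tag IDs across individuals: {tags}")


# The default scenario mirrors the field deployment: a 6 h session with the
# focal female visiting at the observed mean rate; the male's rate is set
# equal to the female's absent a reported value; one experimenter test tag.
FEMALE_TAG = TagID("00F17A23C5")
MALE_TAG = TagID("00A94D10B7")
TEST_TAG = TagID("00DEADBEEF")

DEFAULT_SCENARIO = SiteScenario(
    duration_s=6 * 3600.0,
    individuals=(
        Individual(FEMALE_TAG, Role.TARGET, VisitProcessParams(visit_rate_per_hr=8.96)),
        Individual(MALE_TAG, Role.NONTARGET, VisitProcessParams(visit_rate_per_hr=8.96)),
        Individual(TEST_TAG, Role.TEST),
    ),
    overlap_prob=0.05,
    seed=0,
)


def _poisson_arrivals(rate_per_s: float, duration_s: float, rng: np.random.Generator) -> list[float]:
    """Homogeneous Poisson arrival times on [0, duration_s) via exponential gaps."""
    times: list[float] = []
    if rate_per_s <= 0:
        return times
    t = rng.exponential(1.0 / rate_per_s)
    while t < duration_s:
        times.append(t)
        t += rng.exponential(1.0 / rate_per_s)
    return times


def simulate_visits(
    params: VisitProcessParams,
    duration_s: float,
    seed: Optional[int] = None,
    *,
    tag_id: TagID = FEMALE_TAG,
    rng: Optional[np.random.Generator] = None,
) -> list[PresenceInterval]:
    """Simulate one individual's presence intervals over a deployment.

    Poisson arrivals are thinned so that a new visit never starts before
    ``min_gap_s`` after the previous visit ended (which also keeps intervals
    disjoint when ``min_gap_s == 0``); dwells beyond the deployment end are
    truncated.  Identical seeds give identical output.
    """
    if duration_s <= 0:
        raise ValueError(f"duration_s must be positive, got {duration_s}")
    if rng is None:
        rng = np.random.default_rng(seed)
    rate_per_s = params.visit_rate_per_hr / 3600.0
    scale = params.dwell_mean_s - params.dwell_min_s
    intervals: list[PresenceInterval] = []
    prev_end = -float("inf")
    for start in _poisson_arrivals(rate_per_s, duration_s, rng):
        if start < prev_end + params.min_gap_s:
            continue  # bird still present (or too soon after): not a new visit
        dwell = params.dwell_min_s + (rng.exponential(scale) if scale > 0 else 0.0)
        if dwell <= 0:  # degenerate zero-dwell params: skip zero-length presence
            continue
        end = min(start + dwell, duration_s)
        if end <= start:
            continue
        intervals.append(PresenceInterval(tag_id, start, end))
        prev_end = end
    return intervals


def _resolve_overlaps(intervals: list[PresenceInterval]) -> list[PresenceInterval]:
    """Sort and drop intervals that would overlap an earlier-kept one (per tag)."""
    kept: list[PresenceInterval] = []
    prev_end = -float("inf")
    for iv in sorted(intervals, key=lambda iv: (iv.start_s, iv.end_s)):
        if iv.start_s < prev_end:
            continue
        kept.append(iv)
        prev_end = iv.end_s
    return kept


def simulate_site(scenario: SiteScenario) -> dict[TagID, list[PresenceInterval]]:
    """Simulate every individual at one nest; returns per-tag sorted intervals.

    Each individual gets an independent child generator spawned from the
    scenario seed, so the output is fully determined by the scenario.  After
    the independent draws, each non-target visit is rescheduled (with
    probability ``overlap_prob``) to start together with a uniformly chosen
    target visit, creating the two-tags-in-range situations in which the
    reader records nothing.
    """
    root = np.random.SeedSequence(scenario.seed)
    children = root.spawn(len(scenario.individuals))

    presence: dict[TagID, list[PresenceInterval]] = {}
    rngs: dict[TagID, np.random.Generator] = {}
    for ind, child in zip(scenario.individuals, children):
        rng = np.random.default_rng(child)
        rngs[ind.tag_id] = rng
        if ind.role is Role.TEST:
            end_swipe_start = max(0.0, scenario.duration_s - TEST_SWIPE_DWELL_S)
            ivs = [
                PresenceInterval(
                    ind.tag_id, 0.0, min(TEST_SWIPE_DWELL_S, scenario.duration_s)
                )
            ]
            if end_swipe_start > TEST_SWIPE_DWELL_S:
                ivs.append(
                    PresenceInterval(ind.tag_id, end_swipe_start, scenario.duration_s)
                )
            presence[ind.tag_id] = ivs
        else:
            assert ind.params is not None
            presence[ind.tag_id] = simulate_visits(
                ind.params, scenario.duration_s, tag_id=ind.tag_id, rng=rng
            )

    target_ivs = [
        iv
        for ind in scenario.individuals
        if ind.role is Role.TARGET
        for iv in presence[ind.tag_id]
    ]
    if target_ivs and scenario.overlap_prob > 0:
        for ind in scenario.individuals:
            if ind.role is not Role.NONTARGET:
                continue
            rng = rngs[ind.tag_id]
            moved: list[PresenceInterval] = []
            for iv in presence[ind.tag_id]:
                if rng.random() < scenario.overlap_prob:
                    anchor = target_ivs[int(rng.integers(len(target_ivs)))]
                    start = anchor.start_s
                    end = min(start + iv.duration_s, scenario.duration_s)
                    if end > start:
                        moved.append(PresenceInterval(ind.tag_id, start, end))
                else:
                    moved.append(iv)
            presence[ind.tag_id] = _resolve_overlaps(moved)
    return presence


def write_presence_csv(presence: Mapping[TagID, Sequence[PresenceInterval]]) -> str:
    """Serialize ground-truth intervals as headerless CSV: tag_id,start_s,end_s."""
    lines = [
        f"{iv.tag_id.value},{iv.start_s:.6f},{iv.end_s:.6f}"
        for tag in sorted(presence)
        for iv in presence[tag]
    ]
    return "".join(line + "\n" for line in lines)


def parse_presence_csv(source: Iterable[str]) -> dict[TagID, list[PresenceInterval]]:
    presence: dict[TagID, list[PresenceInterval]] = {}
    for raw in source:
        line = raw.strip()
        if not line:
            continue
        tag_text, start_text, end_text = line.split(",")
        iv = PresenceInterval(TagID(tag_text), float(start_text), float(end_text))
        presence.setdefault(iv.tag_id, []).append(iv)
    for ivs in presence.values():
        ivs.sort(key=lambda iv: iv.start_s)
    return presence
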