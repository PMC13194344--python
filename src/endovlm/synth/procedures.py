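"""Activity-level procedure sampling.

A procedure is a temporally ordered sequence of activities.  Activity states
are drawn from a recurring catalogue of anatomical configurations (landmark
subsets) and evolve according to the configured Markov chain; the anatomical
configuration is constant within an activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import GeneratorConfig
from ..textproc import (GROUP_TO_CAVITY, KEYWORDS, LANDMARK_GROUPS,
                        LANDMARK_NAMES, MOVEMENT_DIRECTIONS)


@dataclass
class LandmarkVector:
    bits: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.int8)
        if not np.all((bits == 0) | (bits == 1)):
            raise ValueError("landmark vector must be binary")
        self.bits = bits

    def __len__(self) -> int:
        return int(self.bits.size)

    def to_string(self) -> str:
        return "".join(str(int(b)) for b in self.bits)

    @classmethod
    def from_string(cls, s: str) -> "LandmarkVector":
        return cls(np.array([int(ch) for ch in s], dtype=np.int8))


@dataclass
class Activity:
    index: int
    state_id: int
    landmark_vector: LandmarkVector
    start_time: float
    end_time: float
    main_cavity: str
    landmark_group: str
    movement_direction: str
    keyword: str
    report_sentence: str

    def __post_init__(self) -> None:
        if self.end_time <= self.start_time:
            raise ValueError("activity must have positive duration")

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


def build_state_catalogue(config: GeneratorConfig,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """Balanced catalogue of landmark configurations.

    Class j is a member of round(freq_j * n_states) states, spread so state
    sizes stay balanced.  Under the (uniform-stationary) default transition
    matrix this makes the expected activity-level class frequency equal the
    configured one.  Deterministic given the config seed.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xCA7]))
    S, C = config.n_states, config.n_classes
    members = np.round(np.asarray(config.class_frequencies) * S).astype(int)
    members = np.clip(members, 1, S)   # every class occurs somewhere
    for _ in range(32):
        cat = np.zeros((S, C), dtype=np.int8)
        counts = np.zeros(S, dtype=int)
        order = np.argsort(-members, kind="stable")
        for j in order:
            # the m_j least-populated states, random tie-break
            keys = counts + rng.uniform(0, 0.5, size=S)
            chosen = np.argsort(keys)[: members[j]]
            cat[chosen, j] = 1
            counts[chosen] += 1
        distinct = len({tuple(row) for row in cat}) == S
        if distinct and np.all(cat.sum(axis=1) > 0):
            return cat
    return cat  # balanced but possibly with duplicate states; still valid


def movement_direction(prev_state: int, next_state: int) -> str:
    """Deterministic direction label for a state transition."""
    if prev_state == next_state:
        return "hold"
    return MOVEMENT_DIRECTIONS[(next_state - prev_state) % 4]


def _report_sentence(keyword: str, names: list[str]) -> str:
    # keyword-initial: the spoken keyword anchors the sentence opening, so a
    # keyword start token directly conditions the rest of the generation
    what = " and ".join(names) if names else "the operative field"
    return f"{keyword} the {what} region"


def sample_procedure(config: GeneratorConfig, procedure_seed: int
                     ) -> list[Activity]:
    """Sample one procedure's activity sequence from the Markov chain."""
    config.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0xAC7, procedure_seed]))
    catalogue = build_state_catalogue(config)
    tm = config.get_transition_matrix()
    lo, hi = config.activities_per_procedure
    n_act = int(rng.integers(lo, hi + 1))
    states = np.empty(n_act, dtype=int)
    states[0] = rng.integers(config.n_states)
    for i in range(1, n_act):
        states[i] = rng.choice(config.n_states, p=tm[states[i - 1]])
    durations = rng.uniform(*config.activity_duration, size=n_act)

    activities: list[Activity] = []
    t = 0.0
    for i, (s, dur) in enumerate(zip(states, durations)):
        bits = catalogue[s]
        present = np.flatnonzero(bits)
        names = [LANDMARK_NAMES[j] for j in present if j < len(LANDMARK_NAMES)]
        group = (LANDMARK_GROUPS[present[0]] if present.size
                 else "group of the nasal vestibule")
        cavity = GROUP_TO_CAVITY[group]
        direction = ("advance" if i == 0
                     else movement_direction(int(states[i - 1]), int(s)))
        keyword = str(rng.choice(KEYWORDS))
        activities.append(Activity(
            index=i, state_id=int(s),
            landmark_vector=LandmarkVector(bits.copy()),
            start_time=t, end_time=t + float(dur),
            main_cavity=cavity, landmark_group=group,
            movement_direction=direction, keyword=keyword,
            report_sentence=_report_sentence(keyword, names)))
        t += float(dur)
    return activities
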