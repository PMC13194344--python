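"""Generator configuration and its validation rules."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

# Default per-class marginal frequencies (fraction of activities in which the
# class is visible).  Chosen on the 1/n_states grid so a balanced 20-state
# catalogue can realise them exactly in expectation, with a long-tail profile:
# two head classes above 20% and five tail classes at 5%.
DEFAULT_CLASS_FREQUENCIES: tuple[float, ...] = (
    0.15, 0.25, 0.25, 0.20, 0.15, 0.15, 0.10, 0.10,
    0.10, 0.10, 0.05, 0.05, 0.05, 0.05, 0.10, 0.05,
)


def default_transition_matrix(n_states: int, p_forward: float = 0.7) -> np.ndarray:
    """Ring-biased row-stochastic matrix: each state prefers its successor.

    The bias makes the next anatomical configuration predictable above
    chance (the property the description-prediction task relies on) while
    every state remains reachable, and the matrix is doubly stochastic so
    the stationary distribution over states is uniform.
    """
    if n_states < 2:
        raise ValueError("need at least 2 activity states")
    rest = (1.0 - p_forward) / (n_states - 1)
    mat = np.full((n_states, n_states), rest)
    for s in range(n_states):
        mat[s, (s + 1) % n_states] = p_forward
    return mat


@dataclass
class GeneratorConfig:
    n_classes: int = 16
    class_frequencies: tuple[float, ...] = DEFAULT_CLASS_FREQUENCIES
    n_procedures: int = 5
    activities_per_procedure: tuple[int, int] = (30, 50)
    frames_per_second: float = 5.0
    activity_duration: tuple[float, float] = (2.0, 8.0)
    n_states: int = 20
    transition_matrix: np.ndarray | None = None
    image_size: int = 64
    noise_sd: float = 0.05           # pixel noise, fraction of full scale
    missing_channel_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.class_frequencies = tuple(float(f) for f in self.class_frequencies)
        if self.transition_matrix is not None:
            self.transition_matrix = np.asarray(self.transition_matrix, float)
        self.validate()

    def validate(self) -> None:
        if self.n_classes <= 0 or self.n_procedures <= 0 or self.n_states <= 0:
            raise ValueError("all counts must be positive")
        if len(self.class_frequencies) != self.n_classes:
            raise ValueError("class_frequencies length must equal n_classes")
        freqs = np.asarray(self.class_frequencies)
        if np.any(freqs < 0) or np.any(freqs > 1):
            raise ValueError("class frequencies must lie in [0, 1]")
        if not (np.any(freqs > 0.20) and np.any(freqs < 0.10)):
            raise ValueError(
                "long-tail violated: need at least one class >0.20 "
                "and one <0.10")
        if self.activities_per_procedure[0] < 1 or \
                self.activities_per_procedure[0] > self.activities_per_procedure[1]:
            raise ValueError("invalid activities_per_procedure range")
        lo, hi = self.activity_duration
        if lo <= 0 or lo > hi:
            raise ValueError("invalid activity_duration range")
        if self.frames_per_second <= 0:
            raise ValueError("frames_per_second must be positive")
        if not (0.0 <= self.missing_channel_rate < 1.0):
            raise ValueError("missing_channel_rate must be in [0, 1)")
        if self.image_size < 4 * int(np.ceil(np.sqrt(self.n_classes))):
            raise ValueError("image too small to separate the class glyphs")
        tm = self.get_transition_matrix()
        if tm.shape != (self.n_states, self.n_states):
            raise ValueError("transition_matrix shape must be (n_states, n_states)")
        if np.any(tm < 0) or np.any(np.abs(tm.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition_matrix rows must sum to 1 +/- 1e-9")

    def get_transition_matrix(self) -> np.ndarray:
        if self.transition_matrix is None:
            return default_transition_matrix(self.n_states)
        return self.transition_matrix

    # -- serialisation --------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["transition_matrix"] is not None:
            d["transition_matrix"] = np.asarray(d["transition_matrix"]).tolist()
        d["class_frequencies"] = list(d["class_frequencies"])
        d["activities_per_procedure"] = list(d["activities_per_procedure"])
        d["activity_duration"] = list(d["activity_duration"])
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("class_frequencies", "activities_per_procedure",
                    "activity_duration"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("transition_matrix") is not None:
            d["transition_matrix"] = np.asarray(d["transition_matrix"], float)
        return cls(**d)

    @classmethod
    def load(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
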