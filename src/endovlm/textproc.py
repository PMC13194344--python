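"""Text plumbing shared by every language pathway.

Covers the closed-world vocabulary, word-level tokenisation, the 5-slot
structured-description template (step count, main cavity, landmark group,
landmarks, movement direction), procedure/observation time tokens, and the
report context window that keeps the 250 most recent tokens of the
(keyword, sentence) history.

Word-level tokenisation is deliberate: the corpus is small and closed, so
sub-word schemes would only add moving parts.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

# --- domain name tables ------------------------------------------------------
# Natural-language names for the anatomical landmark classes of functional
# endoscopic sinus surgery (FESS).  The class count is configurable; these are
# the default 16.  Names never contain the template separators (" , ", " and ").

LANDMARK_NAMES: tuple[str, ...] = (
    "nose entry",
    "middle nasal meatus",
    "middle nasal concha",
    "processus uncinatus",
    "maxillary sinus orifice",
    "bulla ethmoidalis",
    "set of choanae",
    "ethmoidal labyrinth",
    "orbital plate of the ethmoid",
    "sphenoidal sinus",
    "sphenoethmoidal recess",
    "cranial base",
    "anterior ethmoidal artery",
    "posterior ethmoidal artery",
    "inferior nasal concha",
    "frontal recess",
)

# per-class landmark group (coarse anatomical grouping used in slot 3)
LANDMARK_GROUPS: tuple[str, ...] = (
    "group of the nasal vestibule",
    "group of the medial nasal concha",
    "group of the medial nasal concha",
    "group of the ethmoidal labyrinth",
    "group of the maxillary sinus",
    "group of the ethmoidal labyrinth",
    "group of the nasal vestibule",
    "group of the ethmoidal labyrinth",
    "group of the ethmoidal labyrinth",
    "group of the sphenoidal sinus",
    "group of the sphenoidal sinus",
    "group of the skull base",
    "group of the skull base",
    "group of the skull base",
    "group of the medial nasal concha",
    "group of the frontal recess",
)

GROUP_TO_CAVITY: dict[str, str] = {
    "group of the nasal vestibule": "nasal cavity",
    "group of the medial nasal concha": "nasal cavity",
    "group of the ethmoidal labyrinth": "ethmoidal sinus",
    "group of the maxillary sinus": "maxillary sinus",
    "group of the sphenoidal sinus": "sphenoidal sinus",
    "group of the skull base": "sphenoidal sinus",
    "group of the frontal recess": "frontal sinus",
}

MOVEMENT_DIRECTIONS: tuple[str, ...] = (
    "advance", "retract", "rotate-left", "rotate-right", "hold")

KEYWORDS: tuple[str, ...] = (
    "inspect", "resect", "irrigate", "palpate", "coagulate", "suction")

PAD, START, END, UNK = "<pad>", "<s>", "</s>", "<unk>"
TIME_TOKENS: tuple[str, ...] = tuple(f"<t{i:03d}>" for i in range(101))

_WORD_RE = re.compile(r"[\w<>:/-]+|[^\w\s]")


def word_tokens(text: str) -> list[str]:
    """Split text into word/punctuation tokens (specials stay atomic)."""
    return _WORD_RE.findall(text)


def keyword_start_token(keyword: str) -> str:
    return f"<kw:{keyword}>"


@dataclass
class TokenSequence:
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)

    def __len__(self) -> int:
        return int(self.ids.size)

    def __eq__(self, other) -> bool:
        return isinstance(other, TokenSequence) and np.array_equal(self.ids, other.ids)


class Vocabulary:
    """Invertible token <-> dense-id mapping with special tokens.

    Ordering is deterministic: corpus tokens by (frequency desc, token asc),
    then PAD/START/END/UNK, the 101 time tokens and one start token per
    keyword appended at the end.
    """

    def __init__(self, tokens: Sequence[str]):
        self.id_to_token: list[str] = list(tokens)
        self.token_to_id: dict[str, int] = {t: i for i, t in enumerate(tokens)}
        if len(self.token_to_id) != len(self.id_to_token):
            raise ValueError("duplicate tokens in vocabulary")
        for sp in (PAD, START, END, UNK):
            if sp not in self.token_to_id:
                raise ValueError(f"special token {sp!r} missing")

    def __len__(self) -> int:
        return len(self.id_to_token)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id

    def id(self, token: str) -> int:
        return self.token_to_id.get(token, self.token_to_id[UNK])

    def token(self, idx: int) -> str:
        return self.id_to_token[idx]

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def start_id(self) -> int:
        return self.token_to_id[START]

    @property
    def end_id(self) -> int:
        return self.token_to_id[END]

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.token_to_id, fh, indent=0)

    @classmethod
    def load(cls, path) -> "Vocabulary":
        with open(path) as fh:
            mapping = json.load(fh)
        tokens = [t for t, _ in sorted(mapping.items(), key=lambda kv: kv[1])]
        return cls(tokens)


def build_vocab(corpus: Iterable[str], min_count: int = 1,
                keywords: Sequence[str] = KEYWORDS) -> Vocabulary:
    """Word-level vocabulary from a text corpus.

    Tokens with frequency below `min_count` are dropped (they map to UNK at
    encode time); specials, time tokens and per-keyword start tokens are
    appended after the corpus tokens.
    """
    counts: dict[str, int] = {}
    n_docs = 0
    for text in corpus:
        n_docs += 1
        for tok in word_tokens(text):
            counts[tok] = counts.get(tok, 0) + 1
    if n_docs == 0:
        raise ValueError("empty corpus")
    kept = sorted((t for t, c in counts.items() if c >= min_count),
                  key=lambda t: (-counts[t], t))
    specials = [PAD, START, END, UNK, *TIME_TOKENS,
                *(keyword_start_token(k) for k in keywords)]
    tokens = kept + [s for s in specials if s not in set(kept)]
    return Vocabulary(tokens)


def tokenize(text: str, vocab: Vocabulary) -> TokenSequence:
    return TokenSequence(np.array([vocab.id(t) for t in word_tokens(text)],
                                  dtype=np.int64))


def detokenize(seq: TokenSequence | Sequence[int], vocab: Vocabulary) -> str:
    ids = seq.ids if isinstance(seq, TokenSequence) else seq
    return " ".join(vocab.token(int(i)) for i in ids)


# --- structured description template ----------------------------------------

_EMPTY_LANDMARKS = "nothing"

_TEMPLATE = ("step {step} : in the {cavity} , at the {group} , "
             "seeing {landmarks} , moving {direction}")

_PARSE_RE = re.compile(
    r"^step (\d+) : in the (.+?) , at the (.+?) , "
    r"seeing (.+?) , moving (\S+)$")


@dataclass
class StructuredDescription:
    step_count: int
    main_cavity: str
    landmark_group: str
    landmarks: list[str]
    movement_direction: str
    rendered_text: str = field(default="")

    def __post_init__(self) -> None:
        if not self.rendered_text:
            names = " and ".join(self.landmarks) if self.landmarks else _EMPTY_LANDMARKS
            self.rendered_text = _TEMPLATE.format(
                step=self.step_count, cavity=self.main_cavity,
                group=self.landmark_group, landmarks=names,
                direction=self.movement_direction)

    def slots(self) -> tuple:
        return (self.step_count, self.main_cavity, self.landmark_group,
                tuple(self.landmarks), self.movement_direction)


def render_structured_description(activity, step_count: int | None = None,
                                  landmark_names: Sequence[str] = LANDMARK_NAMES
                                  ) -> StructuredDescription:
    """Render an activity into the templated 5-slot description.

    `activity` needs the fields main_cavity, landmark_group,
    movement_direction and landmark_vector (a binary sequence).
    """
    bits = np.asarray(activity.landmark_vector.bits)
    if bits.size > len(landmark_names):
        raise ValueError(
            f"no names for {bits.size} classes (have {len(landmark_names)})")
    names = [landmark_names[j] for j in np.flatnonzero(bits)]
    step = activity.index + 1 if step_count is None else step_count
    return StructuredDescription(
        step_count=step, main_cavity=activity.main_cavity,
        landmark_group=activity.landmark_group, landmarks=names,
        movement_direction=activity.movement_direction)


def parse_structured_description(text: str) -> StructuredDescription:
    """Inverse of the template: recover the 5 slots from rendered text."""
    m = _PARSE_RE.match(text.strip())
    if m is None:
        raise ValueError(f"not a structured description: {text!r}")
    step, cavity, group, names, direction = m.groups()
    landmarks = [] if names == _EMPTY_LANDMARKS else names.split(" and ")
    return StructuredDescription(
        step_count=int(step), main_cavity=cavity, landmark_group=group,
        landmarks=landmarks, movement_direction=direction)


# --- context window and time tokens -----------------------------------------

@dataclass
class ContextWindow:
    pairs: list[tuple[str, str]]
    keyword_current: str
    token_limit: int = 250


def make_context_window(history: Sequence[tuple[str, str]], k_t: str,
                        vocab: Vocabulary, token_limit: int = 250
                        ) -> TokenSequence:
    """Serialize the (keyword, sentence) history plus the current keyword and
    keep only the most recent `token_limit` tokens (left truncation)."""
    if token_limit <= 0:
        raise ValueError("token_limit must be positive")
    ids: list[int] = []
    for kw, sentence in history:
        ids.append(vocab.id(keyword_start_token(kw)))
        ids.extend(tokenize(sentence, vocab).ids.tolist())
    ids.append(vocab.id(keyword_start_token(k_t)))
    return TokenSequence(np.array(ids[-token_limit:], dtype=np.int64))


def encode_time(t_procedure: float, t_observation: float,
                vocab: Vocabulary | None = None):
    """Quantize the two time fractions to 2 decimals (round half to even) and
    map each to one token from the 101-token time vocabulary.

    Returns the two token strings, or a TokenSequence if a vocabulary is given.
    """
    toks = []
    for t in (t_procedure, t_observation):
        if not (0.0 <= t <= 1.0):
            raise ValueError(f"time fraction out of [0, 1]: {t}")
        # numpy round = round half to even; scale to integer percent
        toks.append(TIME_TOKENS[int(np.round(t * 100))])
    if vocab is None:
        return tuple(toks)
    return TokenSequence(np.array([vocab.id(t) for t in toks], dtype=np.int64))
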