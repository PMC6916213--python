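"""From raw notes to model inputs.

All of a patient's notes from one calendar day are merged into a single
document (pulmonary first, then radiology, then cardiology), tokenized,
integer-encoded against a frequency-ranked vocabulary and padded/truncated to
a fixed length ``T``.  Each daily sample carries a death-window label: with
initial window length ``B`` days and ``P`` classes, a sample written ``d``
days before death falls in class ``min(floor(d / B), P - 1)`` — class 0 is
the B-day window adjacent to death and the last class absorbs everything
older than ``(P - 1) * B`` days.
"""

from __future__ import annotations

import datetime
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus_io import NOTE_TYPES, NoteDocument
from .errors import ConfigurationError, ValidationError

PAD_ID = 0
OOV_ID = 1

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lowercase and split on runs of non-alphanumeric characters."""
    return _TOKEN_RE.findall(text.lower())


@dataclass(frozen=True)
class Vocabulary:
    """Token -> id map with id 0 reserved for padding and 1 for out-of-vocabulary."""

    token_to_id: Mapping[str, int]

    @property
    def size(self) -> int:
        """Number of ids in use, including the two reserved ids."""
        return len(self.token_to_id) + 2

    def __getitem__(self, token: str) -> int:
        return self.token_to_id.get(token, OOV_ID)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id


def build_vocab(texts: Iterable[str], max_size: int) -> Vocabulary:
    """Rank tokens by corpus frequency and keep the top ``max_size - 2``.

    Ties are broken lexicographically so vocabulary construction is
    deterministic.  Ids 0 and 1 stay reserved; real tokens get 2, 3, ...
    """
    if max_size < 3:
        raise ConfigurationError("vocabulary size must be at least 3")
    counts: Counter[str] = Counter()
    for text in texts:
        counts.update(tokenize(text))
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    kept = ranked[: max_size - 2]
    return Vocabulary({tok: i + 2 for i, (tok, _) in enumerate(kept)})


def merge_day_notes(notes: Sequence[NoteDocument]) -> str:
    """Concatenate one patient-day's notes: pulmonary, radiology, cardiology.

    Within a note type the original (chronological) order is preserved;
    texts are joined with single spaces.
    """
    if not notes:
        raise ValidationError("cannot merge an empty set of notes")
    rank = {t: i for i, t in enumerate(NOTE_TYPES)}
    ordered = sorted(notes, key=lambda n: rank[n.note_type])  # stable within type
    return " ".join(n.text for n in ordered)


def encode_pad(tokens: Sequence[str], vocab: Vocabulary, max_len: int) -> np.ndarray:
    """Map tokens to ids (unknown -> 1), truncate to the first ``max_len``,
    post-pad with 0."""
    if max_len < 1:
        raise ConfigurationError("max_len must be >= 1")
    ids = np.full(max_len, PAD_ID, dtype=np.int32)
    for i, tok in enumerate(tokens[:max_len]):
        ids[i] = vocab[tok]
    return ids


@dataclass(frozen=True)
class WindowLabelSpec:
    """Death-window labelling rule: B-day classes counted back from death."""

    window_days: int
    n_classes: int

    def __post_init__(self) -> None:
        if self.window_days < 1 or self.n_classes < 1:
            raise ConfigurationError("window_days and n_classes must be >= 1")

    def label(self, days_before_death: int) -> int:
        if days_before_death < 0:
            raise ValidationError("days_before_death must be non-negative")
        return min(days_before_death // self.window_days, self.n_classes - 1)

    def one_hot(self, labels: Sequence[int]) -> np.ndarray:
        out = np.zeros((len(labels), self.n_classes))
        out[np.arange(len(labels)), np.asarray(labels, dtype=int)] = 1.0
        return out


@dataclass(frozen=True, eq=False)
class DailySample:
    """One patient-day: merged note text encoded to exactly T token ids."""

    patient_id: str
    day: datetime.date
    days_before_death: int
    token_ids: np.ndarray
    label: int


def make_samples(
    notes: Sequence[NoteDocument],
    death_dates: Mapping[str, datetime.date],
    vocab: Vocabulary,
    spec: WindowLabelSpec,
    max_len: int,
) -> list[DailySample]:
    """One sample per patient-day with at least one note, sorted by (patient, day)."""
    by_day: dict[tuple[str, datetime.date], list[NoteDocument]] = {}
    for note in notes:
        if note.patient_id not in death_dates:
            raise ValidationError(f"patient {note.patient_id!r} has no death record")
        by_day.setdefault((note.patient_id, note.date), []).append(note)
    samples = []
    for (pid, day) in sorted(by_day):
        dbd = (death_dates[pid] - day).days
        if dbd < 0:
            raise ValidationError(f"patient {pid!r}: note dated after death")
        text = merge_day_notes(by_day[(pid, day)])
        samples.append(
            DailySample(
                patient_id=pid,
                day=day,
                days_before_death=dbd,
                token_ids=encode_pad(tokenize(text), vocab, max_len),
                label=spec.label(dbd),
            )
        )
    return samples


def sample_matrix(samples: Sequence[DailySample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into (ids, labels) arrays for training."""
    ids = np.stack([s.token_ids for s in samples])
    labels = np.array([s.label for s in samples], dtype=np.int64)
    return ids, labels
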