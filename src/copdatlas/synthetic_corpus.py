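"""Synthetic longitudinal clinical-note corpora with planted temporal themes.

Real end-of-life note corpora are confidential, so every downstream stage is
exercised on generated data instead.  The generator plants the structure the
pipeline is supposed to recover:

* each patient's history is laid out on a days-before-death axis (day 0 =
  death) and partitioned into latent *stages* by fixed day boundaries;
* every stage owns a private theme vocabulary, disjoint from the other
  stages and from a shared background vocabulary;
* each sentence (10-14 words by default) draws ``round(theme_word_fraction
  * len)`` words from its stage vocabulary and the rest from background;
* note days arrive as a per-day Poisson draw whose rate is multiplied by
  ``density_boost_near_death`` inside the final stage, emulating the
  clinical-visit densification that precedes death;
* each note day carries 1-3 notes across the pulmonary / radiology /
  cardiology types.

Everything is driven by one seeded generator: the same seed reproduces the
corpus byte for byte.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import corpus_io
from .corpus_io import DeathRecord, NoteDocument, NOTE_TYPES
from .errors import ConfigurationError, ValidationError
from .segmentation import Segment

#: All simulated patients die on this date; only day offsets before death matter.
SIMULATION_DEATH_DATE = datetime.date(2017, 6, 30)

_BACKGROUND = (
    "patient exam history stable noted review chest clinic visit report "
    "impression findings study normal prior daily status mild moderate today "
    "present left right lower upper compared unchanged follow plan continue "
    "assessment course chart record test result value range seen"
).split()

_STAGE_THEMES = (
    # early disease: smoker's cough, mild airway findings
    "cough smoker wheeze sputum bronchitis spirometry albuterol mild-obstruction "
    "fev1-preserved exercise walking breathless-on-exertion".split(),
    # progressing disease: exacerbations, escalating therapy
    "dyspnea exacerbation inhaler steroid hypoxia oxygen-requirement prednisone "
    "hyperinflation air-trapping nebulizer admission tiotropium".split(),
    # terminal stage: failure, intensive and comfort care
    "hospice palliative intubation tachycardia cor-pulmonale respiratory-failure "
    "bipap morphine cyanosis hypercapnia sedation comfort-measures".split(),
)


def default_stage_vocabularies(n_stages: int) -> tuple[tuple[str, ...], ...]:
    """Curated clinical theme words for up to three stages, generated beyond."""
    vocabs = [tuple(words) for words in _STAGE_THEMES[:n_stages]]
    for s in range(len(vocabs), n_stages):
        vocabs.append(tuple(f"stage{s}term{j:02d}" for j in range(12)))
    return tuple(vocabs)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-structure corpus generator.

    ``stage_boundaries_days`` lists the stage edges in days before death,
    strictly decreasing and ending at 0; with ``horizon_days`` they induce
    ``n_stages = len(stage_boundaries_days)`` intervals: the oldest stage
    spans ``[horizon, boundaries[0])`` and the final stage touches death.
    """

    n_patients: int = 200
    stage_boundaries_days: tuple[int, ...] = (120, 60, 0)
    horizon_days: int = 180
    vocab_background: tuple[str, ...] = tuple(_BACKGROUND)
    vocab_stage: tuple[tuple[str, ...], ...] = field(
        default_factory=lambda: default_stage_vocabularies(3)
    )
    sentence_len_range: tuple[int, int] = (10, 14)
    sentences_per_note_range: tuple[int, int] = (2, 4)
    notes_per_day_rate: float = 0.06
    density_boost_near_death: float = 2.0
    theme_word_fraction: float = 0.4
    seed: int = 0

    @property
    def n_stages(self) -> int:
        return len(self.stage_boundaries_days)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if self.n_stages < 2:
            raise ConfigurationError("at least 2 stages are required")
        b = self.stage_boundaries_days
        if b[-1] != 0 or any(x <= y for x, y in zip(b, b[1:])):
            raise ConfigurationError(
                "stage_boundaries_days must be strictly decreasing and end at 0"
            )
        if self.horizon_days <= b[0]:
            raise ConfigurationError("horizon_days must exceed the oldest stage boundary")
        if len(self.vocab_stage) != self.n_stages:
            raise ConfigurationError("need one stage vocabulary per stage")
        pools = [set(self.vocab_background)] + [set(v) for v in self.vocab_stage]
        for i, a in enumerate(pools):
            for bset in pools[i + 1 :]:
                if a & bset:
                    raise ConfigurationError(
                        f"vocabularies must be pairwise disjoint; overlap: {sorted(a & bset)[:5]}"
                    )
        lo, hi = self.sentence_len_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("sentence_len_range must satisfy 1 <= min <= max")
        if not 0.0 <= self.theme_word_fraction <= 1.0:
            raise ConfigurationError("theme_word_fraction must be in [0, 1]")
        if self.notes_per_day_rate <= 0 or self.density_boost_near_death <= 0:
            raise ConfigurationError("rates must be positive")

    def stage_of(self, days_before_death: int) -> int:
        """Planted stage index (0 = oldest) for a day offset before death."""
        return sum(1 for b in self.stage_boundaries_days if b > days_before_death)


@dataclass
class SyntheticCorpus:
    """Generated notes plus the planted ground truth used only for evaluation."""

    notes: list[NoteDocument]
    deaths: list[DeathRecord]
    note_stages: list[int]
    stage_boundaries_days: tuple[int, ...]
    horizon_days: int

    @property
    def death_dates(self) -> dict[str, datetime.date]:
        return corpus_io.death_date_map(self.deaths)


def _make_sentence(rng: np.random.Generator, cfg: SyntheticConfig, stage: int) -> str:
    lo, hi = cfg.sentence_len_range
    length = int(rng.integers(lo, hi + 1))
    n_theme = round(cfg.theme_word_fraction * length)
    words = list(rng.choice(cfg.vocab_stage[stage], size=n_theme, replace=True)) + list(
        rng.choice(cfg.vocab_background, size=length - n_theme, replace=True)
    )
    order = rng.permutation(length)
    return " ".join(words[i] for i in order) + "."


def _make_note_text(rng: np.random.Generator, cfg: SyntheticConfig, stage: int) -> str:
    lo, hi = cfg.sentences_per_note_range
    n_sent = int(rng.integers(lo, hi + 1))
    return " ".join(_make_sentence(rng, cfg, stage) for _ in range(n_sent))


def generate_corpus(config: SyntheticConfig) -> SyntheticCorpus:
    """Generate a corpus with planted stage structure; deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    notes: list[NoteDocument] = []
    stages: list[int] = []
    deaths: list[DeathRecord] = []
    final_stage = config.n_stages - 1
    for p in range(config.n_patients):
        pid = f"P{p:04d}"
        deaths.append(DeathRecord(pid, SIMULATION_DEATH_DATE))
        note_days: list[int] = []
        for day in range(1, config.horizon_days + 1):
            stage = config.stage_of(day)
            rate = config.notes_per_day_rate
            if stage == final_stage:
                rate *= config.density_boost_near_death
            if rng.poisson(rate) > 0:
                note_days.append(day)
        if not note_days:  # every patient must contribute at least one note
            note_days.append(int(rng.integers(1, config.horizon_days + 1)))
        for day in note_days:
            stage = config.stage_of(day)
            date = SIMULATION_DEATH_DATE - datetime.timedelta(days=day)
            n_notes = int(rng.integers(1, 4))
            types = rng.choice(len(NOTE_TYPES), size=n_notes, replace=False)
            for t in sorted(types):
                notes.append(
                    NoteDocument(
                        patient_id=pid,
                        date=date,
                        note_type=NOTE_TYPES[t],
                        text=_make_note_text(rng, config, stage),
                    )
                )
                stages.append(stage)
    return SyntheticCorpus(
        notes=notes,
        deaths=deaths,
        note_stages=stages,
        stage_boundaries_days=tuple(config.stage_boundaries_days),
        horizon_days=config.horizon_days,
    )


def corpus_truth_segments(corpus: SyntheticCorpus, patient_id: str) -> list[Segment]:
    """Planted stage windows for one patient as days-before-death segments.

    Boundaries ``[b0 > b1 > ... > 0]`` over horizon H yield the partition
    ``[H, b0), [b0, b1), ..., [b_{k-2}, 0)``, ordered oldest first.
    """
    if patient_id not in {d.patient_id for d in corpus.deaths}:
        raise KeyError(f"unknown patient {patient_id!r}")
    edges = [corpus.horizon_days, *corpus.stage_boundaries_days]
    return [Segment(start, end) for start, end in zip(edges, edges[1:])]


def write_corpus(corpus: SyntheticCorpus, outdir: str | Path) -> dict[str, Path]:
    """Write notes.jsonl, deaths.csv and the truth sidecar truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "notes": outdir / "notes.jsonl",
        "deaths": outdir / "deaths.csv",
        "truth": outdir / "truth.json",
    }
    corpus_io.write_notes(corpus.notes, paths["notes"])
    corpus_io.write_deaths(corpus.deaths, paths["deaths"])
    truth = {
        "stage_boundaries_days": list(corpus.stage_boundaries_days),
        "horizon_days": corpus.horizon_days,
        "note_stages": corpus.note_stages,
    }
    paths["truth"].write_text(json.dumps(truth, indent=1) + "\n", encoding="utf-8")
    return paths


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
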