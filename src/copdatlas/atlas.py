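"""The COPD atlas: per-segment LDA themes, representative sentences, spiral.

For each of the ``n`` (default 7) most recent irregular time-lapse segments
before death, the atlas fits a latent Dirichlet allocation model over the
segment's sentences, takes the top ``m`` words of each topic as *theme
words*, and keeps the top ``k`` (default 10) *representative sentences* — a
sentence qualifies when the fraction of its tokens that are theme words of
its best-matching topic reaches 30%, i.e. roughly 3-4 theme words in a
10-14-word sentence.  The result is rendered as JSON, as a Markdown report,
and as a spiral timeline (SVG) where the equal-window baseline partition is
drawn in green against the irregular segments in red.
"""

from __future__ import annotations

import datetime
import json
import math
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.decomposition import LatentDirichletAllocation

from .corpus_io import NoteDocument
from .errors import ValidationError
from .preprocess import tokenize
from .segmentation import Segment, most_recent

_SENTENCE_RE = re.compile(r"[.!?]+(?:\s+|$)")


def split_sentences(text: str) -> list[str]:
    """Split on sentence-final punctuation followed by whitespace or end."""
    parts = [p.strip() for p in _SENTENCE_RE.split(text)]
    return [p for p in parts if p]


@dataclass(frozen=True)
class ThemeModel:
    """A fitted per-segment LDA: theme words and topic mixtures."""

    topic_words: tuple[tuple[str, ...], ...]
    topic_word_dist: np.ndarray  # (n_topics, n_features), rows sum to 1
    doc_topic: np.ndarray  # (n_sentences, n_topics)
    feature_names: tuple[str, ...]

    @property
    def n_topics(self) -> int:
        return len(self.topic_words)


def fit_lda(
    sentences: Sequence[str],
    n_topics: int,
    m_theme_words: int = 10,
    seed: int = 0,
) -> ThemeModel:
    """Fit sentence-level LDA and extract the top-m theme words per topic.

    Ties in topic-word probability break lexicographically so the theme-word
    lists are deterministic for a fixed seed.
    """
    if len(sentences) < n_topics:
        raise ValidationError(
            f"segment has {len(sentences)} sentences but {n_topics} topics were "
            "requested; merge segments or lower n_topics"
        )
    token_lists = [tokenize(s) for s in sentences]
    features = sorted({tok for toks in token_lists for tok in toks})
    if not features:
        raise ValidationError("segment sentences contain no tokens")
    index = {tok: j for j, tok in enumerate(features)}
    counts = np.zeros((len(sentences), len(features)))
    for r, toks in enumerate(token_lists):
        for tok in toks:
            counts[r, index[tok]] += 1.0
    lda = LatentDirichletAllocation(n_components=n_topics, random_state=seed)
    doc_topic = lda.fit_transform(counts)
    dist = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    m = min(m_theme_words, len(features))
    topic_words = tuple(
        tuple(tok for _, tok in sorted(zip(-row, features))[:m]) for row in dist
    )
    return ThemeModel(
        topic_words=topic_words,
        topic_word_dist=dist,
        doc_topic=doc_topic,
        feature_names=tuple(features),
    )


def theme_hits(tokens: Sequence[str], theme_words: Sequence[str]) -> int:
    """Distinct theme words present in the sentence (repeats count once)."""
    return len(set(tokens) & set(theme_words))


def is_representative(
    tokens: Sequence[str], theme_words: Sequence[str], threshold: float = 0.30
) -> tuple[bool, float]:
    """Decide whether a sentence represents a topic.

    The score is (distinct theme-word hits) / (sentence length in tokens);
    the sentence is representative when the score reaches the threshold
    (inclusive — 3 hits in a 10-word sentence qualifies at 30%).
    """
    if not tokens:
        raise ValidationError("cannot score an empty sentence")
    fraction = theme_hits(tokens, theme_words) / len(tokens)
    return fraction >= threshold, fraction


@dataclass(frozen=True)
class RepresentativeSentence:
    """A sentence kept for the atlas, with its theme-word score."""

    text: str
    token_count: int
    theme_hits: int
    fraction: float
    topic_id: int
    segment_ref: tuple[int, int]  # (start_days_before_death, end_days_before_death)


def top_k_sentences(
    sentences: Sequence[str],
    theme: ThemeModel,
    k: int = 10,
    threshold: float = 0.30,
    segment_ref: tuple[int, int] = (0, 0),
) -> list[RepresentativeSentence]:
    """Rank representative sentences: fraction desc, hits desc, first seen.

    Each sentence is attributed to its best topic (most distinct hits, lower
    topic id on ties); exact duplicate texts are kept once.
    """
    scored: list[tuple[float, int, int, RepresentativeSentence]] = []
    seen: set[str] = set()
    for pos, sentence in enumerate(sentences):
        if sentence in seen:
            continue
        seen.add(sentence)
        tokens = tokenize(sentence)
        if not tokens:
            continue
        hits_by_topic = [theme_hits(tokens, tw) for tw in theme.topic_words]
        topic = int(np.argmax(hits_by_topic))
        hits = hits_by_topic[topic]
        fraction = hits / len(tokens)
        if fraction >= threshold:
            scored.append(
                (
                    -fraction,
                    -hits,
                    pos,
                    RepresentativeSentence(
                        text=sentence,
                        token_count=len(tokens),
                        theme_hits=hits,
                        fraction=fraction,
                        topic_id=topic,
                        segment_ref=segment_ref,
                    ),
                )
            )
    scored.sort(key=lambda item: item[:3])
    return [item[3] for item in scored[:k]]


@dataclass(frozen=True)
class AtlasSegment:
    segment: Segment
    theme_words: tuple[tuple[str, ...], ...]
    sentences: tuple[RepresentativeSentence, ...]
    n_candidate_sentences: int


@dataclass(frozen=True)
class AtlasDocument:
    """Ordered (death-first) atlas segments plus the parameters that built them."""

    segments: tuple[AtlasSegment, ...]
    n_recent: int
    k: int
    n_topics: int
    m_theme_words: int
    threshold: float
    seed: int


def segment_sentences(
    segment: Segment,
    notes: Sequence[NoteDocument],
    death_dates: Mapping[str, datetime.date],
    note_types: Sequence[str] | None = None,
) -> list[str]:
    """All sentences from notes written inside the segment's day range."""
    out: list[str] = []
    for note in notes:
        if note_types is not None and note.note_type not in note_types:
            continue
        dbd = (death_dates[note.patient_id] - note.date).days
        if segment.contains(dbd):
            out.extend(split_sentences(note.text))
    return out


def build_atlas(
    segments: Sequence[Segment],
    notes: Sequence[NoteDocument],
    death_dates: Mapping[str, datetime.date],
    n_recent: int = 7,
    k: int = 10,
    n_topics: int = 5,
    m_theme_words: int = 10,
    threshold: float = 0.30,
    seed: int = 0,
    note_types: Sequence[str] | None = None,
) -> AtlasDocument:
    """Theme the ``n_recent`` most recent segments and pick their sentences.

    A segment with no sentences is kept with an empty list (and a warning);
    a segment with fewer sentences than topics is themed with as many topics
    as it can support.
    """
    chosen = most_recent(segments, n_recent)
    atlas_segments: list[AtlasSegment] = []
    for seg in chosen:
        sentences = segment_sentences(seg, notes, death_dates, note_types)
        ref = (seg.start_days_before_death, seg.end_days_before_death)
        if not sentences:
            warnings.warn(f"segment {ref} has no sentences; kept empty", stacklevel=2)
            atlas_segments.append(AtlasSegment(seg, (), (), 0))
            continue
        theme = fit_lda(sentences, min(n_topics, len(sentences)), m_theme_words, seed)
        top = top_k_sentences(sentences, theme, k=k, threshold=threshold, segment_ref=ref)
        atlas_segments.append(
            AtlasSegment(seg, theme.topic_words, tuple(top), len(sentences))
        )
    return AtlasDocument(
        segments=tuple(atlas_segments),
        n_recent=n_recent,
        k=k,
        n_topics=n_topics,
        m_theme_words=m_theme_words,
        threshold=threshold,
        seed=seed,
    )


def atlas_to_dict(atlas: AtlasDocument) -> dict:
    return {
        "params": {
            "n_recent": atlas.n_recent,
            "k": atlas.k,
            "n_topics": atlas.n_topics,
            "m_theme_words": atlas.m_theme_words,
            "threshold": atlas.threshold,
            "seed": atlas.seed,
        },
        "segments": [
            {
                "start_days_before_death": s.segment.start_days_before_death,
                "end_days_before_death": s.segment.end_days_before_death,
                "theme_words": [list(tw) for tw in s.theme_words],
                "n_candidate_sentences": s.n_candidate_sentences,
                "sentences": [
                    {
                        "text": r.text,
                        "token_count": r.token_count,
                        "theme_hits": r.theme_hits,
                        "fraction": round(r.fraction, 6),
                        "topic_id": r.topic_id,
                    }
                    for r in s.sentences
                ],
            }
            for s in atlas.segments
        ],
    }


def write_atlas_json(atlas: AtlasDocument, path: str | Path) -> None:
    Path(path).write_text(json.dumps(atlas_to_dict(atlas), indent=1) + "\n", encoding="utf-8")


def write_markdown_report(atlas: AtlasDocument, path: str | Path) -> None:
    """Textual atlas: one section per segment, theme words then sentences."""
    lines = ["# COPD atlas", ""]
    for s in atlas.segments:
        seg = s.segment
        lines.append(
            f"## {seg.start_days_before_death}-{seg.end_days_before_death} days before death"
        )
        for t, words in enumerate(s.theme_words):
            lines.append(f"- topic {t}: {', '.join(words)}")
        lines.append("")
        for r_i, r in enumerate(s.sentences, start=1):
            lines.append(
                f"{r_i}. {r.text} ({r.theme_hits}/{r.token_count} theme words)"
            )
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# spiral timeline rendering

def _spiral_point(
    days: float, days_per_turn: float, r0: float, r_per_turn: float,
    cx: float, cy: float, r_offset: float = 0.0,
) -> tuple[float, float]:
    theta = 2.0 * math.pi * days / days_per_turn
    r = r0 + r_per_turn * days / days_per_turn + r_offset
    # clockwise from 12 o'clock, death at the centre
    return cx + r * math.sin(theta), cy - r * math.cos(theta)


def render_spiral(
    atlas: AtlasDocument,
    baseline_segments: Sequence[Segment],
    path: str | Path,
    days_per_turn: int = 360,
    size: int = 800,
) -> None:
    """Write a deterministic SVG spiral timeline.

    Days before death grow outward along an Archimedean spiral (one
    revolution = ``days_per_turn`` days, death at the centre).  The
    equal-window baseline is the green line; the atlas' irregular segments
    are the red line, offset outward, with a marker and day-range label at
    each segment boundary.
    """
    if not atlas.segments:
        raise ValidationError("cannot render an empty atlas")
    horizon = max(
        [s.segment.start_days_before_death for s in atlas.segments]
        + [s.start_days_before_death for s in baseline_segments]
    )
    cx = cy = size / 2.0
    turns = max(1.0, horizon / days_per_turn)
    r_per_turn = (size / 2.0 - 60.0) / turns
    r0 = 20.0

    def pts(d0: int, d1: int, offset: float) -> str:
        step = max(1, (d1 - d0) // 200)
        days = list(range(d0, d1, step)) + [d1]
        coords = (
            _spiral_point(d, days_per_turn, r0, r_per_turn, cx, cy, offset)
            for d in days
        )
        return " ".join(f"{x:.2f},{y:.2f}" for x, y in coords)

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{size}" height="{size}" '
        f'viewBox="0 0 {size} {size}">',
        f'<rect width="{size}" height="{size}" fill="white"/>',
        f'<circle cx="{cx:.2f}" cy="{cy:.2f}" r="3" fill="black"/>',
        f'<text x="{cx + 6:.2f}" y="{cy - 6:.2f}" font-size="12">death</text>',
    ]
    for seg in baseline_segments:
        parts.append(
            f'<polyline fill="none" stroke="green" stroke-width="2" points="'
            f'{pts(seg.end_days_before_death, seg.start_days_before_death, 0.0)}"/>'
        )
        x, y = _spiral_point(seg.start_days_before_death, days_per_turn, r0, r_per_turn, cx, cy)
        parts.append(f'<circle cx="{x:.2f}" cy="{y:.2f}" r="2.5" fill="green"/>')
    for s in atlas.segments:
        seg = s.segment
        parts.append(
            f'<polyline fill="none" stroke="red" stroke-width="2.5" points="'
            f'{pts(seg.end_days_before_death, seg.start_days_before_death, 10.0)}"/>'
        )
        x, y = _spiral_point(seg.start_days_before_death, days_per_turn, r0, r_per_turn, cx, cy, 10.0)
        parts.append(f'<circle cx="{x:.2f}" cy="{y:.2f}" r="3.5" fill="red"/>')
        lx, ly = _spiral_point(
            (seg.start_days_before_death + seg.end_days_before_death) / 2.0,
            days_per_turn, r0, r_per_turn, cx, cy, 24.0,
        )
        parts.append(
            f'<text x="{lx:.2f}" y="{ly:.2f}" font-size="11" fill="red" '
            f'text-anchor="middle">{seg.start_days_before_death}-'
            f'{seg.end_days_before_death}d</text>'
        )
    parts.append("</svg>")
    Path(path).write_text("\n".join(parts) + "\n", encoding="utf-8")
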