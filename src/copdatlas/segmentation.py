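"""Irregular time-lapse segments on the days-before-death axis.

A trained progression model emits, over the ``N`` consecutive initial windows
of ``B`` days each (window 0 adjacent to death, indices increasing backward in
time), a binary boundary signal: 1 at window ``j`` means a new segment starts
there.  Consecutive windows up to the next 1 are merged into one irregular
*time-lapse segment*.  This module converts signals to segments, selects the
most recent ``n`` segments, and builds the equal-window baseline partition
against which the irregular segmentation is compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class Segment:
    """A half-open day interval before death: ``[start, end)`` with start > end.

    ``start_days_before_death`` is the older edge (inclusive, larger offset),
    ``end_days_before_death`` the newer edge (exclusive, smaller offset);
    ``end == 0`` means the segment touches death.
    """

    start_days_before_death: int
    end_days_before_death: int
    member_windows: tuple[int, ...] = ()
    sample_refs: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not (self.start_days_before_death > self.end_days_before_death >= 0):
            raise ValidationError(
                f"segment requires start > end >= 0, got "
                f"[{self.start_days_before_death}, {self.end_days_before_death})"
            )

    @property
    def length_days(self) -> int:
        return self.start_days_before_death - self.end_days_before_death

    def contains(self, days_before_death: int) -> bool:
        return self.end_days_before_death <= days_before_death < self.start_days_before_death


@dataclass(frozen=True)
class SegmentationResult:
    """Segments produced from one boundary signal over B-day initial windows."""

    segments: tuple[Segment, ...]
    window_days: int
    signal: tuple[int, ...]


def signal_to_segments(signal: Sequence[int], window_days: int) -> SegmentationResult:
    """Merge consecutive initial windows into segments at each 1 in ``signal``.

    ``signal[j]`` refers to the j-th B-day window before death (window 0
    closest to death).  Each maximal run of windows beginning at a 1 becomes
    one segment covering ``[run_end * B, run_start * B)`` days before death.
    The signal must open a segment at window 0.
    """
    sig = [int(s) for s in signal]
    if any(s not in (0, 1) for s in sig):
        raise ValidationError("signal entries must be 0 or 1")
    if not sig or sig[0] != 1:
        raise ValidationError("signal must be non-empty and start with 1")
    starts = [j for j, s in enumerate(sig) if s == 1]
    ends = starts[1:] + [len(sig)]
    segments = tuple(
        Segment(
            start_days_before_death=e * window_days,
            end_days_before_death=s * window_days,
            member_windows=tuple(range(s, e)),
        )
        for s, e in zip(starts, ends)
    )
    return SegmentationResult(segments=segments, window_days=window_days, signal=tuple(sig))


def segments_to_signal(result: SegmentationResult) -> tuple[int, ...]:
    """Inverse of :func:`signal_to_segments` (bijection check helper)."""
    n = sum(len(seg.member_windows) for seg in result.segments)
    sig = [0] * n
    for seg in result.segments:
        sig[seg.member_windows[0]] = 1
    return tuple(sig)


def most_recent(segments: Sequence[Segment], n: int) -> list[Segment]:
    """The ``n`` segments closest to death, death-first; all if fewer than n."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    ordered = sorted(segments, key=lambda s: s.end_days_before_death)
    return ordered[:n]


def equal_window_baseline(horizon_days: int, window_days: int) -> list[Segment]:
    """Consecutive equal B-day segments from death backward over the horizon.

    The oldest window is shortened when the horizon is not a multiple of B.
    This is the regional-classifier baseline partition.
    """
    if horizon_days < 1 or window_days < 1:
        raise ValidationError("horizon_days and window_days must be >= 1")
    segments = []
    end = 0
    idx = 0
    while end < horizon_days:
        start = min(end + window_days, horizon_days)
        segments.append(Segment(start, end, member_windows=(idx,)))
        end = start
        idx += 1
    return segments


def group_samples_by_window(
    days_before_death: Sequence[int], window_days: int, n_windows: int | None = None
) -> list[np.ndarray]:
    """Pool sample indices into consecutive B-day windows before death.

    Returns one index array per window (window 0 adjacent to death).  Samples
    beyond ``n_windows * B`` days, if a window count is given, fall into the
    last window; otherwise the window count is taken from the data.
    """
    offsets = np.asarray(days_before_death, dtype=int)
    if offsets.size == 0:
        raise ValidationError("no samples to group")
    idx = offsets // window_days
    if n_windows is None:
        n_windows = int(idx.max()) + 1
    idx = np.minimum(idx, n_windows - 1)
    return [np.flatnonzero(idx == j) for j in range(n_windows)]
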