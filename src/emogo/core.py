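"""Shared domain types and conventions.

Conventions used throughout the package:

* sample indices are 0-based;
* time windows given in milliseconds convert to samples via
  ``sample = round(ms * rate / 1000)`` (round-half-to-even);
* continuous-time intervals (epochs, bad spans) are half-open
  ``[start, end)`` in samples;
* all voltages are microvolts (µV) in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

#: Standard 32-channel actiCAP labels (10-20 system).
ACTICAP32: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FT9",
    "FC5", "FC1", "FC2", "FC6", "FT10", "T7", "C3", "Cz",
    "C4", "T8", "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "O1", "Oz", "O2",
)

#: Channels dropped before analysis (poor signal quality at the mastoid /
#: fronto-temporal fringe in pediatric caps).
DEFAULT_EXCLUDED: frozenset[str] = frozenset({"FT9", "TP9", "TP10", "FT10"})

CONDITIONS = ("Go", "NoGo")
EMOTIONS = ("angry", "neutral", "happy")


def ms_to_sample(ms: float, rate: float) -> int:
    """Convert a time in ms to a 0-based sample index (round-half-to-even)."""
    return int(round(ms * rate / 1000.0))


@dataclass(frozen=True)
class ChannelLayout:
    """Electrode montage: full label set, online reference/ground, exclusions."""

    names: tuple[str, ...] = ACTICAP32
    reference: str = "Cz"
    ground: str = "Fpz"
    excluded: frozenset[str] = DEFAULT_EXCLUDED

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel labels must be unique")
        unknown = set(self.excluded) - set(self.names)
        if unknown:
            raise ValueError(f"excluded labels not in montage: {sorted(unknown)}")

    @property
    def retained(self) -> tuple[str, ...]:
        """Labels kept for analysis, in montage order."""
        return tuple(n for n in self.names if n not in self.excluded)

    def index(self, name: str) -> int:
        """Row index of ``name`` in the retained data matrix."""
        try:
            return self.retained.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not among retained channels") from None


@dataclass(frozen=True)
class EventMarker:
    """Stimulus-onset marker tied to one task trial."""

    sample: int
    trial_id: int
    condition: str  # "Go" | "NoGo"
    emotion: str    # "angry" | "neutral" | "happy"
    identity: str   # face model id
    is_practice: bool = False


@dataclass(frozen=True)
class Span:
    """Half-open sample interval ``[start, end)`` with a label."""

    start: int
    end: int
    kind: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("span end must exceed start")

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class RawRecording:
    """Continuous multichannel EEG in µV.

    ``data`` has one row per retained channel (montage order), ``events``
    are stimulus markers, ``annotations`` are labelled spans (used by the
    synthetic generator for ground-truth blink/artifact locations).
    """

    data: np.ndarray            # (n_channels, n_samples) µV
    rate: float = 500.0
    layout: ChannelLayout = field(default_factory=ChannelLayout)
    events: list[EventMarker] = field(default_factory=list)
    annotations: list[Span] = field(default_factory=list)
    filter_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.layout.retained):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but layout retains "
                f"{len(self.layout.retained)} channels"
            )
        n = self.data.shape[1]
        for ev in self.events:
            if not 0 <= ev.sample < n:
                raise ValueError(f"event at sample {ev.sample} outside recording (n={n})")
        self.annotations = sorted(self.annotations, key=lambda s: s.start)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.layout.index(name)]

    def copy_with(self, data: np.ndarray, extra_log: dict | None = None) -> "RawRecording":
        log = list(self.filter_log) + ([extra_log] if extra_log else [])
        return RawRecording(
            data=data, rate=self.rate, layout=self.layout,
            events=list(self.events), annotations=list(self.annotations),
            filter_log=log,
        )


def merge_spans(spans: Iterable[Span]) -> list[Span]:
    """Merge overlapping/touching spans of any kind into a sorted list.

    Overlapping spans of differing kinds keep the kind of the earlier one;
    exclusion logic only cares about coverage.
    """
    ordered = sorted(spans, key=lambda s: (s.start, s.end))
    merged: list[Span] = []
    for s in ordered:
        if merged and s.start <= merged[-1].end:
            last = merged[-1]
            merged[-1] = Span(last.start, max(last.end, s.end), last.kind)
        else:
            merged.append(s)
    return merged


def spans_cover(spans: Sequence[Span], sample: int) -> bool:
    return any(s.start <= sample < s.end for s in spans)
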