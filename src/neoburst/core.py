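"""Core containers for EEG signals and burst / inter-burst annotations.

The discontinuous (tracé discontinu) EEG of very preterm infants alternates
between higher-voltage bursts and low-voltage inter-burst intervals.  The
package works with three containers:

* :class:`EEGRecord` — multichannel µV samples at a fixed sampling rate,
* :class:`Annotation` — a per-sample ternary label stream
  (burst / inter-burst / undefined) at its own rate,
* :class:`IntervalList` — the interval (start, end, label) serialisation of
  an annotation, with half-open ``[start, end)`` semantics in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Per-sample label codes.  UNDEFINED marks non-consensus or unannotated time.
BURST: int = 1
INTER_BURST: int = 0
UNDEFINED: int = -1

LABEL_NAMES = {BURST: "burst", INTER_BURST: "inter_burst", UNDEFINED: "undefined"}
NAME_LABELS = {v: k for k, v in LABEL_NAMES.items()}


@dataclass
class EEGRecord:
    """Multichannel EEG: ``samples`` is (n_channels, n_times) in µV."""

    samples: np.ndarray
    fs: float
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.samples.shape[0]} channel rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in record") from None
        return self.samples[idx]


@dataclass
class Annotation:
    """Per-sample labels over {BURST, INTER_BURST, UNDEFINED} at rate ``fs``."""

    labels: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8).ravel()
        if self.labels.size == 0:
            raise ValueError("annotation must contain at least one sample")
        if self.fs <= 0:
            raise ValueError("label sampling rate must be positive")
        bad = ~np.isin(self.labels, (BURST, INTER_BURST, UNDEFINED))
        if bad.any():
            raise ValueError(f"invalid label value(s): {set(self.labels[bad])}")

    @property
    def duration_s(self) -> float:
        return self.labels.size / self.fs

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of samples with a consensus (non-UNDEFINED) label."""
        return self.labels != UNDEFINED

    def resample(self, fs_new: float) -> "Annotation":
        """Nearest-neighbour label lookup on a new sample grid.

        Labels are categorical, so interpolation is meaningless; each new
        sample takes the label of the nearest original sample centre.
        """
        n_new = int(round(self.duration_s * fs_new))
        t_new = (np.arange(n_new) + 0.5) / fs_new
        idx = np.clip((t_new * self.fs).astype(int), 0, self.labels.size - 1)
        return Annotation(self.labels[idx], fs_new)

    def segments(self) -> list[tuple[int, int, int]]:
        """Maximal constant-label runs as (start_idx, end_idx, label), half-open."""
        lab = self.labels
        change = np.flatnonzero(np.diff(lab)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [lab.size]))
        return [(int(s), int(e), int(lab[s])) for s, e in zip(starts, ends)]


@dataclass
class IntervalList:
    """Sorted, non-overlapping labelled intervals ``(start_s, end_s, label)``."""

    intervals: list[tuple[float, float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        iv = sorted(self.intervals, key=lambda t: t[0])
        for start, end, label in iv:
            if not start < end:
                raise ValueError(f"empty or inverted interval ({start}, {end})")
            if label not in LABEL_NAMES:
                raise ValueError(f"invalid interval label {label}")
        for (s0, e0, _), (s1, e1, _) in zip(iv, iv[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping intervals at {s1:.6g} s")
        self.intervals = [(float(s), float(e), int(l)) for s, e, l in iv]

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


def annotation_to_intervals(a: Annotation) -> IntervalList:
    """Convert labels to intervals; UNDEFINED runs are omitted."""
    out = []
    for s, e, lab in a.segments():
        if lab != UNDEFINED:
            out.append((s / a.fs, e / a.fs, lab))
    return IntervalList(out)


def intervals_to_annotation(iv: IntervalList, fs: float, duration_s: float) -> Annotation:
    """Rasterise intervals to per-sample labels; uncovered time is UNDEFINED.

    A sample at index n covers [n/fs, (n+1)/fs); it takes an interval's label
    when its centre falls inside the half-open interval.
    """
    n = int(round(duration_s * fs))
    labels = np.full(n, UNDEFINED, dtype=np.int8)
    centres = (np.arange(n) + 0.5) / fs
    for start, end, lab in iv:
        labels[(centres >= start) & (centres < end)] = lab
    return Annotation(labels, fs)
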