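"""Reading/writing EEG and annotations; montage and consensus construction.

EEG comes in as EDF (read through :mod:`mne`) or a plain CSV of µV samples
(one column per channel, ``# fs=<Hz>`` comment line above the header).
Annotations travel as interval CSVs with columns ``start_s,end_s,label`` and
half-open ``[start, end)`` semantics.

A minimal EDF writer is included so synthetic fixtures can round-trip
through the same binary format as clinical exports; it emits standard
16-bit EDF readable by any EDF tool.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    UNDEFINED,
    Annotation,
    EEGRecord,
    IntervalList,
    LABEL_NAMES,
    NAME_LABELS,
)

#: The eight bipolar derivations used for preterm burst analysis.
DEFAULT_MONTAGE: list[tuple[str, str]] = [
    ("F4", "C4"), ("C4", "O2"), ("F3", "C3"), ("C3", "O1"),
    ("T4", "C4"), ("C4", "Cz"), ("Cz", "C3"), ("C3", "T3"),
]


# ---------------------------------------------------------------------------
# EEG I/O
# ---------------------------------------------------------------------------

def load_eeg(path: str | Path, format: str | None = None) -> EEGRecord:
    """Load an EEG record from an EDF or CSV file.

    Parameters
    ----------
    path : path to the file.
    format : ``"edf"`` or ``"csv"``; inferred from the suffix when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "edf":
        return _load_edf(path)
    if fmt == "csv":
        return _load_csv(path)
    raise ValueError(f"unknown EEG format {fmt!r} (expected 'edf' or 'csv')")


def save_eeg(record: EEGRecord, path: str | Path, format: str | None = None) -> None:
    """Write an EEG record as EDF or CSV (format inferred from suffix)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "edf":
        write_edf(record, path)
    elif fmt == "csv":
        _write_csv(record, path)
    else:
        raise ValueError(f"unknown EEG format {fmt!r}")


def _load_csv(path: Path) -> EEGRecord:
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("#") or "fs=" not in first:
        raise ValueError(f"{path}: missing '# fs=<Hz>' header line")
    fs = float(first.split("fs=")[1].split()[0])
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise ValueError(f"{path}: no samples")
    return EEGRecord(df.to_numpy(dtype=float).T, fs, [str(c) for c in df.columns])


def _write_csv(record: EEGRecord, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs:g}\n")
        pd.DataFrame(record.samples.T, columns=record.channel_labels).to_csv(
            fh, index=False
        )


def _load_edf(path: Path) -> EEGRecord:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data(units="uV")
    return EEGRecord(data_uv, float(raw.info["sfreq"]), list(raw.ch_names))


def write_edf(record: EEGRecord, path: str | Path) -> None:
    """Write 16-bit EDF with one 1-second data record per second of signal.

    The record length must be an integer number of seconds and ``fs`` an
    integer rate; amplitudes are quantised onto the per-channel physical
    range (16-bit resolution).
    """
    fs = record.fs
    if fs != int(fs):
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(fs)
    n = record.n_times
    if n % fs:
        raise ValueError("EDF writer requires an integer number of seconds")
    n_rec, ns = n // fs, record.n_channels

    def fixed(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise ValueError(f"EDF field too long: {text!r}")
        return b.ljust(width)

    header = b"".join([
        fixed("0", 8),
        fixed("X X X X", 80),
        fixed("Startdate X X X X", 80),
        fixed("01.01.00", 8),
        fixed("00.00.00", 8),
        fixed(str(256 * (1 + ns)), 8),
        fixed("", 44),
        fixed(str(n_rec), 8),
        fixed("1", 8),
        fixed(str(ns), 4),
    ])

    phys_min = np.floor(record.samples.min(axis=1))
    phys_max = np.ceil(record.samples.max(axis=1))
    same = phys_max <= phys_min
    phys_max[same] = phys_min[same] + 1.0
    dig_min, dig_max = -32768, 32767

    def col(values: list[str], width: int) -> bytes:
        return b"".join(fixed(v, width) for v in values)

    header += col(record.channel_labels, 16)
    header += col([""] * ns, 80)
    header += col(["uV"] * ns, 8)
    header += col([f"{v:g}" for v in phys_min], 8)
    header += col([f"{v:g}" for v in phys_max], 8)
    header += col([str(dig_min)] * ns, 8)
    header += col([str(dig_max)] * ns, 8)
    header += col([""] * ns, 80)
    header += col([str(fs)] * ns, 8)
    header += col([""] * ns, 32)

    gain = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.rint(
        (record.samples - phys_min[:, None]) / gain[:, None] + dig_min
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        # interleave: per data record, all samples of ch0, then ch1, ...
        for r in range(n_rec):
            fh.write(digital[:, r * fs:(r + 1) * fs].tobytes())


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

def derive_bipolar_montage(
    record: EEGRecord, pairs: list[tuple[str, str]] | None = None
) -> EEGRecord:
    """Form bipolar channels ``anode − cathode`` from referential electrodes."""
    if pairs is None:
        pairs = DEFAULT_MONTAGE
    rows, names = [], []
    for anode, cathode in pairs:
        for el in (anode, cathode):
            if el not in record.channel_labels:
                raise KeyError(f"electrode {el!r} not present in record")
        rows.append(record.channel(anode) - record.channel(cathode))
        names.append(f"{anode}-{cathode}")
    return EEGRecord(np.asarray(rows), record.fs, names)


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def consensus_annotation(a1: Annotation, a2: Annotation) -> Annotation:
    """Sample-wise agreement of two reviewers; disagreements become UNDEFINED.

    Only the burst / inter-burst periods where both reviewers agree are kept,
    so downstream training and testing see unambiguous samples only.
    """
    if a1.fs != a2.fs or a1.labels.size != a2.labels.size:
        raise ValueError("annotations must share sampling rate and length")
    agree = (a1.labels == a2.labels) & (a1.labels != UNDEFINED)
    labels = np.where(agree, a1.labels, UNDEFINED)
    return Annotation(labels, a1.fs)


def load_intervals(path: str | Path) -> IntervalList:
    df = pd.read_csv(path)
    missing = {"start_s", "end_s", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        name = str(row["label"])
        if name not in NAME_LABELS:
            raise ValueError(f"{path}: unknown label {name!r}")
        out.append((float(row["start_s"]), float(row["end_s"]), NAME_LABELS[name]))
    return IntervalList(out)


def save_intervals(iv: IntervalList, path: str | Path) -> None:
    pd.DataFrame(
        [(s, e, LABEL_NAMES[l]) for s, e, l in iv],
        columns=["start_s", "end_s", "label"],
    ).to_csv(path, index=False)


def load_annotation(path: str | Path, fs: float, duration_s: float) -> Annotation:
    """Read an interval CSV and rasterise it onto an ``fs`` grid."""
    from .core import intervals_to_annotation

    return intervals_to_annotation(load_intervals(path), fs, duration_s)


def save_annotation(a: Annotation, path: str | Path) -> None:
    from .core import annotation_to_intervals

    save_intervals(annotation_to_intervals(a), path)
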