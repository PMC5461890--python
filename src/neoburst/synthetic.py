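"""Synthetic discontinuous (tracé discontinu) preterm EEG with ground truth.

The generator emulates the statistical structure the detector exploits:
alternating burst / inter-burst segments with right-skewed (log-normal)
duration distributions (median burst 5.7 s, median inter-burst 4.1 s),
inter-bursts as low-amplitude coloured noise with a near-linear log–log
spectrum, and bursts modelled as slow activity transients (SATs): a
dominant high-amplitude delta (0.5–3 Hz) wave carrying broadband coloured
noise and nested faster 3–15 Hz activity that bends the log–log spectral
shape.  Segments are cross-faded so that boundary discontinuities do not
trivially cue the detector.  It also simulates a pair of imperfect human annotators for
consensus and agreement testing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .core import BURST, INTER_BURST, Annotation, EEGRecord


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic record.

    Amplitudes are in µV; ``noise_floor_uv`` is the RMS of the inter-burst
    (background) activity and ``burst_gain`` the burst/inter-burst
    amplitude ratio.  ``burst_bump`` scales the extra band-limited
    3–15 Hz component present during bursts, relative to the burst
    coloured-noise RMS, making burst spectra nonlinear on log–log axes.
    ``slow_wave_gain`` scales the delta-band (0.5–3 Hz) slow wave that
    dominates real bursts (SATs are delta-led events); with
    ``burst_gain=1`` and ``burst_bump=0`` the slow wave is also disabled,
    giving a null record with statistically identical classes.
    ``amplitude_sigma`` is the log-space SD of independent per-segment
    amplitude scaling — real burst (and inter-burst) amplitudes vary
    several-fold between events, so quiet bursts overlap loud inter-bursts
    and no single amplitude feature is sufficient on its own.
    ``sensor_noise_uv`` is state-independent broadband instrument/EMG
    noise, which dominates both states at high frequencies and keeps the
    high-band burst contrast modest, as in real recordings.
    """

    fs: float = 256.0
    duration_s: float = 600.0
    burst_median_s: float = 5.7
    ibi_median_s: float = 4.1
    duration_sigma: float = 0.75
    burst_gain: float = 3.0
    interburst_slope: float = -2.0
    burst_bump: float = 0.1
    slow_wave_gain: float = 1.5
    amplitude_sigma: float = 0.4
    noise_floor_uv: float = 10.0
    sensor_noise_uv: float = 5.0
    crossfade_s: float = 0.25
    seed: int = 0
    channel_label: str = "F4-C4"


def coloured_noise(
    n: int, slope: float, rng: np.random.Generator, fs: float = 256.0
) -> np.ndarray:
    """Unit-RMS Gaussian noise with power-law spectrum |X(f)|² ∝ f^slope."""
    white = rng.standard_normal(n)
    X = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1 / fs)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (slope / 2)
    x = np.fft.irfft(X * shaping, n)
    return x / x.std()


def _segment_plan(config: SyntheticConfig, rng: np.random.Generator):
    """Alternating (label, duration_s) list covering the record."""
    medians = {BURST: config.burst_median_s, INTER_BURST: config.ibi_median_s}
    label = BURST if rng.random() < 0.5 else INTER_BURST
    plan, total = [], 0.0
    while total < config.duration_s:
        dur = float(np.exp(rng.normal(np.log(medians[label]), config.duration_sigma)))
        plan.append((label, dur))
        total += dur
        label = BURST if label == INTER_BURST else INTER_BURST
    return plan


def generate_record(config: SyntheticConfig) -> tuple[EEGRecord, Annotation]:
    """One single-channel discontinuous record with its true annotation."""
    if config.duration_s < 30:
        raise ValueError("duration_s must be at least 30 s")
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n = int(round(config.duration_s * fs))

    # continuous burst and inter-burst processes, mixed by a smooth mask
    ib = coloured_noise(n, config.interburst_slope, rng, fs) * config.noise_floor_uv
    burst_rms = config.noise_floor_uv * config.burst_gain
    b = coloured_noise(n, config.interburst_slope, rng, fs) * burst_rms
    if config.burst_bump > 0:
        sos = sps.butter(4, [3, 15], btype="bandpass", fs=fs, output="sos")
        bump = sps.sosfiltfilt(sos, rng.standard_normal(n))
        b = b + bump / bump.std() * (config.burst_bump * burst_rms)
    # delta-band slow wave of the SAT; vanishes in the null construction
    slow_rms = config.slow_wave_gain * (config.burst_gain - 1) * config.noise_floor_uv
    if slow_rms > 0:
        sos = sps.butter(4, [0.5, 3], btype="bandpass", fs=fs, output="sos")
        slow = sps.sosfiltfilt(sos, rng.standard_normal(n))
        b = b + slow / slow.std() * slow_rms

    labels = np.empty(n, dtype=np.int8)
    log_scale = np.empty(n)
    pos = 0
    for label, dur in _segment_plan(config, rng):
        end = min(n, pos + int(round(dur * fs)))
        labels[pos:end] = label
        log_scale[pos:end] = rng.normal(0, config.amplitude_sigma)
        pos = end
        if pos >= n:
            break

    mask = (labels == BURST).astype(float)
    w = int(round(config.crossfade_s * fs))
    if w > 1:
        win = np.hanning(w)
        kern = win / win.sum()
        mask = np.convolve(mask, kern, mode="same")
        log_scale = np.convolve(log_scale, kern, mode="same")
    x = np.exp(log_scale) * (mask * b + (1 - mask) * ib)
    if config.sensor_noise_uv > 0:
        x = x + rng.standard_normal(n) * config.sensor_noise_uv

    record = EEGRecord(x[None, :], fs, [config.channel_label])
    return record, Annotation(labels, fs)


def generate_dataset(
    config: SyntheticConfig, n_records: int, base_seed: int | None = None
) -> tuple[list[EEGRecord], list[Annotation]]:
    """A cohort of records differing only by seed (base_seed, base_seed+1, …)."""
    base = config.seed if base_seed is None else base_seed
    records, annotations = [], []
    for i in range(n_records):
        rec, ann = generate_record(replace(config, seed=base + i))
        records.append(rec)
        annotations.append(ann)
    return records, annotations


def generate_annotator_pair(
    truth: Annotation,
    boundary_jitter_s: float = 0.5,
    flip_rate: float = 0.05,
    seed: int = 0,
) -> tuple[Annotation, Annotation]:
    """Two imperfect reviewers derived from the true annotation.

    Each reviewer independently jitters every segment boundary by Gaussian
    noise and flips whole segments at random — a crude model of the
    boundary placement and classification disagreements between human
    annotators.  With zero jitter and zero flip rate both copies equal the
    truth.
    """
    if boundary_jitter_s < 0:
        raise ValueError("jitter must be non-negative")
    if not 0 <= flip_rate < 0.5:
        raise ValueError("flip_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    return (
        _corrupt(truth, boundary_jitter_s, flip_rate, rng),
        _corrupt(truth, boundary_jitter_s, flip_rate, rng),
    )


def _corrupt(
    truth: Annotation, jitter_s: float, flip_rate: float, rng: np.random.Generator
) -> Annotation:
    segs = truth.segments()
    n = truth.labels.size
    bounds = np.array([s for s, _, _ in segs[1:]], dtype=float)
    if jitter_s > 0 and bounds.size:
        bounds = bounds + rng.normal(0, jitter_s * truth.fs, bounds.size)
    bounds = np.maximum.accumulate(np.clip(np.round(bounds).astype(int), 0, n))
    edges = np.concatenate(([0], bounds, [n]))
    labels = truth.labels.copy()
    seg_labels = [lab for _, _, lab in segs]
    for i, lab in enumerate(seg_labels):
        if flip_rate > 0 and rng.random() < flip_rate:
            lab = BURST if lab == INTER_BURST else INTER_BURST
        labels[edges[i]:edges[i + 1]] = lab
    return Annotation(labels, truth.fs)
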