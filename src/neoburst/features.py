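"""Feature extraction for burst / inter-burst discrimination in preterm EEG.

Twenty-six per-channel features quantify amplitude, relative spectral power,
spectral shape and frequency-weighted energy:

========================  ======  ========  =========
feature                   count   window    bands
========================  ======  ========  =========
envelope--derivative op.      1   1.5 s MA  0.5–10 Hz
Higuchi fractal dimension     1   1 s       0.5–30 Hz
envelope (|analytic|²)        4   1 s       4 bands
relative PSD power            4   2 s       4 bands
periodic mean frequency       4   2 s       4 bands
instantaneous frequency       4   2 s       4 bands
log–log PSD slope             4   2 s       4 bands
log–log PSD r²                4   2 s       4 bands
========================  ======  ========  =========

The four analysis bands are 0.5–3, 3–8, 8–15 and 15–30 Hz.  Windowed
features are computed with 75% overlap and expanded onto a common 64 Hz
per-sample grid.  The nonlinear energy operator (NLEO) and line-length
measures are provided as single-feature baselines; like the
envelope–derivative operator (EDO) they are computed at the acquisition
rate (256 Hz) because of their sensitivity to sampling frequency, and the
feature stream is then down-sampled to 64 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

#: Common per-sample grid for all features (Hz).
FEATURE_FS: float = 64.0

#: Analysis bands (Hz); they tile the total band contiguously.
DEFAULT_BANDS: list[tuple[float, float]] = [(0.5, 3), (3, 8), (8, 15), (15, 30)]
TOTAL_BAND: tuple[float, float] = (0.5, 30)


@dataclass(frozen=True)
class BandSet:
    """Ordered analysis bands and the total band they are judged against."""

    bands: tuple[tuple[float, float], ...] = tuple(DEFAULT_BANDS)
    total_band: tuple[float, float] = TOTAL_BAND

    def __post_init__(self) -> None:
        for low, high in list(self.bands) + [self.total_band]:
            if not low < high:
                raise ValueError(f"invalid band ({low}, {high})")

    @property
    def tiles_total(self) -> bool:
        """True when the bands cover the total band contiguously."""
        lo, hi = self.total_band
        edges = [lo] + [b[1] for b in self.bands]
        return all(
            b[0] == e for b, e in zip(self.bands, edges)
        ) and edges[-1] == hi

#: Pre-processing band and moving-average length for the energy operators.
ENERGY_BAND: tuple[float, float] = (0.5, 10)
LINE_LENGTH_BAND: tuple[float, float] = (1, 20)
EDO_MA_S: float = 1.5
NLEO_MA_S: float = 1.5
LINE_LENGTH_MA_S: float = 1.0

LOG_FLOOR = 1e-12
DEFAULT_KMAX = 8


@dataclass(frozen=True)
class FeatureSpec:
    """Description of one feature column."""

    name: str
    band: int | None  # index into the band list, or None for broadband
    window_s: float
    summary: str  # MEDIAN | SCALAR | STREAM
    log_transformed: bool

    @property
    def column(self) -> str:
        return self.name if self.band is None else f"{self.name}_b{self.band + 1}"


@dataclass
class FeatureMatrix:
    """Per-sample feature values on the 64 Hz grid."""

    values: np.ndarray  # (n_samples, n_features)
    specs: list[FeatureSpec]
    fs: float = FEATURE_FS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.specs):
            raise ValueError("values must be (n_samples, n_features)")

    @property
    def names(self) -> list[str]:
        return [s.column for s in self.specs]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, columns=self.names)


def default_feature_set(bands: list[tuple[float, float]] | None = None) -> list[FeatureSpec]:
    """The 26-feature default set (EDO, fractal dimension, and six per-band
    families over the four analysis bands)."""
    nb = len(bands or DEFAULT_BANDS)
    specs = [
        FeatureSpec("edo", None, EDO_MA_S, "STREAM", True),
        FeatureSpec("fd", None, 1.0, "SCALAR", False),
    ]
    specs += [FeatureSpec("envelope", b, 1.0, "MEDIAN", True) for b in range(nb)]
    specs += [FeatureSpec("rel_power", b, 2.0, "SCALAR", True) for b in range(nb)]
    specs += [FeatureSpec("mean_freq", b, 2.0, "SCALAR", False) for b in range(nb)]
    specs += [FeatureSpec("inst_freq", b, 2.0, "MEDIAN", False) for b in range(nb)]
    specs += [FeatureSpec("psd_slope", b, 2.0, "SCALAR", False) for b in range(nb)]
    specs += [FeatureSpec("psd_r2", b, 2.0, "SCALAR", False) for b in range(nb)]
    return specs


# ---------------------------------------------------------------------------
# Filtering and resampling
# ---------------------------------------------------------------------------

def bandpass(x: np.ndarray, fs: float, band: tuple[float, float], order: int = 5) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward–backward filtering)."""
    low, high = band
    if not 0 < low < high:
        raise ValueError(f"invalid band {band}")
    if high >= fs / 2:
        raise ValueError(f"band edge {high} Hz at or above Nyquist ({fs / 2} Hz)")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def downsample(x: np.ndarray, fs_in: float, fs_out: float = FEATURE_FS) -> np.ndarray:
    """Anti-alias low-pass then decimate by an integer factor."""
    q = fs_in / fs_out
    if abs(q - round(q)) > 1e-9:
        raise ValueError(f"non-integer decimation factor {q}")
    q = int(round(q))
    if q == 1:
        return np.asarray(x, dtype=float)
    return sps.decimate(np.asarray(x, dtype=float), q, zero_phase=True)


def _energy_prefilter(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Pre-processing filter for the energy operators: 1st-order Butterworth
    high-pass plus 6th-order elliptic low-pass, both zero-phase."""
    low, high = band
    bh, ah = sps.butter(1, low, btype="highpass", fs=fs)
    bl, al = sps.ellip(6, 0.5, 50, high, btype="lowpass", fs=fs)
    return sps.filtfilt(bl, al, sps.filtfilt(bh, ah, np.asarray(x, dtype=float)))


# ---------------------------------------------------------------------------
# Amplitude features
# ---------------------------------------------------------------------------

def analytic(x: np.ndarray) -> np.ndarray:
    """Analytic associate z = x + jH[x] via the FFT Hilbert transform."""
    return sps.hilbert(np.asarray(x, dtype=float))


def envelope(x_band: np.ndarray) -> np.ndarray:
    """Squared magnitude of the analytic signal, a(n) = |z(n)|²."""
    return np.abs(analytic(x_band)) ** 2


# ---------------------------------------------------------------------------
# Spectral features (single window)
# ---------------------------------------------------------------------------

def _band_bins(n: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    """DFT bin indices k (0..N/2-1) with low <= k·fs/N < high (half-open)."""
    k = np.arange(n // 2)
    f = k * fs / n
    return k[(f >= band[0]) & (f < band[1])]


def relative_psd_power(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float],
    total_band: tuple[float, float] = TOTAL_BAND,
) -> float:
    """Band power as a fraction of the total power in ``total_band``.

    P_i = sum_{k in band} |X(k)|² / P_total, on the raw periodogram of the
    window.  An all-zero window has no defined ratio and yields 0.
    """
    x = np.asarray(x, dtype=float)
    X = np.fft.fft(x)
    p = np.abs(X) ** 2
    total = p[_band_bins(x.size, fs, total_band)].sum()
    if total == 0:
        warnings.warn("all-zero window: relative power undefined, emitting 0")
        return 0.0
    return float(p[_band_bins(x.size, fs, band)].sum() / total)


def loglog_psd_fit(
    x: np.ndarray, fs: float, band: tuple[float, float]
) -> tuple[float, float]:
    """Least-squares line on the in-band log–log spectrum.

    Fits Y(k) = c1 + c2·log f_k to Y(k) = log |X(k)|² and returns the slope
    c2 and the coefficient of determination r².  A flat in-band spectrum
    (zero total variance) is a perfect constant fit: r² = 1.
    """
    x = np.asarray(x, dtype=float)
    bins = _band_bins(x.size, fs, band)
    if bins.size < 3:
        raise ValueError(
            f"band {band} Hz has {bins.size} DFT bins in a {x.size}-point window; "
            "need at least 3"
        )
    p = np.abs(np.fft.fft(x)[bins]) ** 2
    Y = np.log(np.maximum(p, LOG_FLOOR))
    F = np.log(bins * fs / x.size)
    slope, intercept = np.polyfit(F, Y, 1)
    resid = Y - (intercept + slope * F)
    ss_tot = np.sum((Y - Y.mean()) ** 2)
    if ss_tot == 0:
        return float(slope), 1.0
    return float(slope), float(1.0 - np.sum(resid**2) / ss_tot)


def mean_frequency(x_band: np.ndarray, fs: float) -> float:
    """Periodic (circular) mean frequency of a band-filtered window.

    The half spectrum k = 0..N/2−1 is mapped onto the unit circle and the
    argument of the power-weighted resultant is scaled back to Hz:
    M = fs/(4π) · { arg[ Σ |X(k)|² e^{j4πk/N} ] mod 2π } ∈ [0, fs/2).
    The circular construction avoids the edge bias of the linear moment.
    """
    x = np.asarray(x_band, dtype=float)
    n = x.size
    p = np.abs(np.fft.fft(x)[: n // 2]) ** 2
    if p.sum() == 0:
        warnings.warn("all-zero window: mean frequency undefined")
        return float("nan")
    z = np.sum(p * np.exp(1j * 4 * np.pi * np.arange(n // 2) / n))
    return float(fs / (4 * np.pi) * (np.angle(z) % (2 * np.pi)))


def instantaneous_frequency(x_band: np.ndarray, fs: float) -> np.ndarray:
    """Per-sample instantaneous frequency by central phase difference.

    f(n) = fs/(4π) · {[φ(n+1) − φ(n−1)] mod 2π} with φ the phase of the
    analytic signal.  Edge samples take the nearest interior value.
    """
    phi = np.angle(analytic(x_band))
    if phi.size < 3:
        raise ValueError("need at least 3 samples")
    f = fs / (4 * np.pi) * ((phi[2:] - phi[:-2]) % (2 * np.pi))
    return np.concatenate(([f[0]], f, [f[-1]]))


# ---------------------------------------------------------------------------
# Fractal dimension
# ---------------------------------------------------------------------------

def higuchi_fd(x: np.ndarray, k_max: int = DEFAULT_KMAX) -> float:
    """Higuchi fractal dimension of a window.

    Curve length at scale k, averaged over offsets m = 1..k,
    L_m(k) = (N−1) / (⌊(N−m)/k⌋ k²) Σ_i |x[m+ik] − x[m+(i−1)k]|,
    scales as L(k) ∝ k^(−D); −D is the slope of log L(k) on log k.
    Returns NaN for a constant window (zero curve length at every scale).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2 * k_max:
        raise ValueError(f"window of {n} samples too short for k_max={k_max}")
    L = np.empty(k_max)
    for k in range(1, k_max + 1):
        Lm = []
        for m in range(1, k + 1):
            n_i = (n - m) // k
            if n_i < 1:
                continue
            # 1-based x[m + ik] is 0-based x[m - 1 + ik]
            idx = m - 1 + np.arange(n_i + 1) * k
            Lm.append((n - 1) / (n_i * k * k) * np.sum(np.abs(np.diff(x[idx]))))
        L[k - 1] = np.mean(Lm)
    if np.any(L <= 0):
        warnings.warn("constant window: fractal dimension undefined")
        return float("nan")
    slope = np.polyfit(np.log(np.arange(1, k_max + 1)), np.log(L), 1)[0]
    return float(-slope)


# ---------------------------------------------------------------------------
# Frequency-weighted energy operators
# ---------------------------------------------------------------------------

def nleo(x: np.ndarray) -> np.ndarray:
    """Absolute nonlinear energy operator |x(n−1)x(n−2) − x(n)x(n−3)|.

    Per-sample stream; the first three samples (undefined lags) take the
    first defined value.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 samples")
    core = np.abs(x[2:-1] * x[1:-2] - x[3:] * x[:-3])
    return np.concatenate((np.full(3, core[0] if core.size else 0.0), core))


def line_length(x: np.ndarray) -> float:
    """Sum of absolute first differences, l = Σ |x(n+1) − x(n)|."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.sum(np.abs(np.diff(x))))


def discrete_hilbert(x: np.ndarray) -> np.ndarray:
    """DFT-based discrete Hilbert transform h(n) (imaginary part of the
    analytic associate)."""
    return np.imag(analytic(x))


def edo(x: np.ndarray, printed_sign: bool = False) -> np.ndarray:
    """Envelope–derivative operator, a non-negative frequency-weighted
    energy measure built from central differences of the analytic signal:

    Γ(n) = ¼[(x(n+1) − x(n−1))² + (h(n+1) − h(n−1))²] = ¼|z(n+1) − z(n−1)|²

    For a tone A·cos(ωn) the output is the constant A²·sin²(ω), so the
    operator vanishes at DC and weights energy by frequency.  With
    ``printed_sign=True`` the cross terms are added instead of subtracted
    (a variant that is maximal at DC; kept for compatibility).  Edge samples
    take the nearest interior value.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    h = discrete_hilbert(x)
    xp, xm = x[2:], x[:-2]
    hp, hm = h[2:], h[:-2]
    if printed_sign:
        core = 0.25 * (xp**2 + xm**2 + hp**2 + hm**2) + 0.5 * (xp * xm + hp * hm)
    else:
        core = 0.25 * ((xp - xm) ** 2 + (hp - hm) ** 2)
    return np.concatenate(([core[0]], core, [core[-1]]))


def moving_average(x: np.ndarray, fs: float, length_s: float) -> np.ndarray:
    """Centred moving average (nearest-edge padding)."""
    w = max(1, int(round(length_s * fs)))
    return uniform_filter1d(np.asarray(x, dtype=float), size=w, mode="nearest")


def _subsample_stream(x: np.ndarray, fs_in: float, fs_out: float = FEATURE_FS) -> np.ndarray:
    """Down-sample an already-smoothed feature stream by plain subsampling.

    The preceding moving average acts as the anti-alias filter; avoiding a
    second filter keeps non-negative streams exactly non-negative.
    """
    q = int(round(fs_in / fs_out))
    return np.asarray(x, dtype=float)[::q]


def edo_stream(x: np.ndarray, fs: float, printed_sign: bool = False) -> np.ndarray:
    """Full EDO feature pipeline at the acquisition rate.

    0.5–10 Hz pre-filter → operator → 1.5 s moving average → 64 Hz stream.
    """
    g = edo(_energy_prefilter(x, fs, ENERGY_BAND), printed_sign=printed_sign)
    return _subsample_stream(moving_average(g, fs, EDO_MA_S), fs)


def nleo_stream(x: np.ndarray, fs: float) -> np.ndarray:
    """Baseline NLEO pipeline: 0.5–10 Hz pre-filter, 1.5 s moving average."""
    g = nleo(_energy_prefilter(x, fs, ENERGY_BAND))
    return _subsample_stream(moving_average(g, fs, NLEO_MA_S), fs)


def line_length_stream(x: np.ndarray, fs: float) -> np.ndarray:
    """Baseline line-length pipeline: 1–20 Hz pre-filter, per-sample |Δx|,
    1 s moving average."""
    xf = _energy_prefilter(x, fs, LINE_LENGTH_BAND)
    d = np.abs(np.diff(xf))
    d = np.concatenate((d, [d[-1]]))
    return _subsample_stream(moving_average(d, fs, LINE_LENGTH_MA_S), fs)


# ---------------------------------------------------------------------------
# Short-time framing
# ---------------------------------------------------------------------------

def frame_count(n_samples: int, fs: float, window_s: float, overlap: float = 0.75) -> int:
    w = int(round(window_s * fs))
    hop = int(round(w * (1 - overlap)))
    if n_samples < w:
        raise ValueError(f"record of {n_samples} samples shorter than one "
                         f"{window_s} s window")
    return (n_samples - w) // hop + 1


def frame_signal(x: np.ndarray, fs: float, window_s: float, overlap: float = 0.75) -> np.ndarray:
    """(n_windows, window_samples) view of overlapping analysis windows."""
    x = np.asarray(x, dtype=float)
    w = int(round(window_s * fs))
    hop = int(round(w * (1 - overlap)))
    if x.size < w:
        raise ValueError(f"record of {x.size} samples shorter than one "
                         f"{window_s} s window")
    return sliding_window_view(x, w)[::hop]


def expand_to_samples(
    values: np.ndarray, n_out: int, fs: float, window_s: float, overlap: float = 0.75
) -> np.ndarray:
    """Map per-window values onto the per-sample grid.

    Each window's value is held over its central hop-length stretch;
    samples before the first / after the last window centre take the
    nearest window's value (piecewise-constant hold with edge fill).
    """
    values = np.asarray(values, dtype=float)
    w = int(round(window_s * fs))
    hop = int(round(w * (1 - overlap)))
    centres_offset = w / 2.0
    m = np.floor((np.arange(n_out) + 0.5 - centres_offset) / hop + 0.5).astype(int)
    return values[np.clip(m, 0, values.size - 1)]


def _fill_nan_nearest(v: np.ndarray) -> np.ndarray:
    """Replace NaNs by the nearest finite value (flat windows etc.)."""
    bad = ~np.isfinite(v)
    if not bad.any():
        return v
    if bad.all():
        return np.zeros_like(v)
    idx = np.arange(v.size)
    v = v.copy()
    v[bad] = np.interp(idx[bad], idx[~bad], v[~bad])
    return v


# ---------------------------------------------------------------------------
# Full extraction pipeline
# ---------------------------------------------------------------------------

def _windowed_spectral(x64: np.ndarray, bands, overlap: float) -> dict[str, np.ndarray]:
    """Vectorised per-window spectral features on the broadband 64 Hz signal."""
    wins = frame_signal(x64, FEATURE_FS, 2.0, overlap)
    n = wins.shape[1]
    P = np.abs(np.fft.fft(wins, axis=1)) ** 2
    total_bins = _band_bins(n, FEATURE_FS, TOTAL_BAND)
    p_tot = P[:, total_bins].sum(axis=1)
    out: dict[str, np.ndarray] = {}
    safe_tot = np.where(p_tot > 0, p_tot, 1.0)
    for b, band in enumerate(bands):
        bins = _band_bins(n, FEATURE_FS, band)
        p_band = P[:, bins].sum(axis=1)
        out[f"rel_power_b{b + 1}"] = np.where(p_tot > 0, p_band / safe_tot, 0.0)
        # least-squares line on the in-band log-log spectrum
        Y = np.log(np.maximum(P[:, bins], LOG_FLOOR))
        F = np.log(bins * FEATURE_FS / n)
        Fc = F - F.mean()
        denom = np.sum(Fc**2)
        slope = Y @ Fc / denom
        resid = Y - Y.mean(axis=1, keepdims=True) - slope[:, None] * Fc
        ss_tot = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = 1.0 - np.sum(resid**2, axis=1) / ss_tot
        r2[ss_tot == 0] = 1.0
        out[f"psd_slope_b{b + 1}"] = slope
        out[f"psd_r2_b{b + 1}"] = r2
    return out


def _windowed_mean_freq(xb: np.ndarray, overlap: float) -> np.ndarray:
    wins = frame_signal(xb, FEATURE_FS, 2.0, overlap)
    n = wins.shape[1]
    P = np.abs(np.fft.fft(wins, axis=1)[:, : n // 2]) ** 2
    z = P @ np.exp(1j * 4 * np.pi * np.arange(n // 2) / n)
    m = FEATURE_FS / (4 * np.pi) * (np.angle(z) % (2 * np.pi))
    m[P.sum(axis=1) == 0] = np.nan
    return m


def _windowed_higuchi(x64: np.ndarray, k_max: int, overlap: float) -> np.ndarray:
    wins = frame_signal(x64, FEATURE_FS, 1.0, overlap)
    n = wins.shape[1]
    logL = np.empty((wins.shape[0], k_max))
    for k in range(1, k_max + 1):
        acc = np.zeros(wins.shape[0])
        for m in range(1, k + 1):
            n_i = (n - m) // k
            idx = m - 1 + np.arange(n_i + 1) * k
            seg = wins[:, idx]
            acc += (n - 1) / (n_i * k * k) * np.sum(np.abs(np.diff(seg, axis=1)), axis=1)
        with np.errstate(divide="ignore"):
            logL[:, k - 1] = np.log(acc / k)
    ks = np.log(np.arange(1, k_max + 1))
    kc = ks - ks.mean()
    with np.errstate(invalid="ignore"):
        d = -(logL @ kc) / np.sum(kc**2)
    d[~np.isfinite(logL).all(axis=1)] = np.nan
    return d


def extract_features(
    x: np.ndarray,
    fs: float,
    bands: list[tuple[float, float]] | None = None,
    overlap: float = 0.75,
    k_max: int = DEFAULT_KMAX,
    printed_edo_sign: bool = False,
) -> FeatureMatrix:
    """Compute the 26-feature matrix for one EEG channel.

    ``x`` is the raw channel at the acquisition rate ``fs`` (µV).  Energy
    operators run at ``fs``; everything else runs on the 64 Hz down-sampled
    signal.  Returns per-sample values on the 64 Hz grid, untransformed
    (see :func:`transform_and_zscore`).
    """
    bands = bands or DEFAULT_BANDS
    specs = default_feature_set(bands)
    x = np.asarray(x, dtype=float)
    x64 = downsample(x, fs, FEATURE_FS)
    n64 = x64.size
    xb_total = bandpass(x64, FEATURE_FS, TOTAL_BAND)

    cols: dict[str, np.ndarray] = {}
    cols["edo"] = edo_stream(x, fs, printed_sign=printed_edo_sign)[:n64]

    fd = _windowed_higuchi(xb_total, k_max, overlap)
    cols["fd"] = expand_to_samples(_fill_nan_nearest(fd), n64, FEATURE_FS, 1.0, overlap)

    spectral = _windowed_spectral(xb_total, bands, overlap)
    for name, vals in spectral.items():
        cols[name] = expand_to_samples(
            _fill_nan_nearest(vals), n64, FEATURE_FS, 2.0, overlap
        )

    for b, band in enumerate(bands):
        xb = bandpass(x64, FEATURE_FS, band)
        env = envelope(xb)
        ew = np.median(frame_signal(env, FEATURE_FS, 1.0, overlap), axis=1)
        cols[f"envelope_b{b + 1}"] = expand_to_samples(ew, n64, FEATURE_FS, 1.0, overlap)

        mf = _windowed_mean_freq(xb, overlap)
        cols[f"mean_freq_b{b + 1}"] = expand_to_samples(
            _fill_nan_nearest(mf), n64, FEATURE_FS, 2.0, overlap
        )

        fi = instantaneous_frequency(xb, FEATURE_FS)
        fw = np.median(frame_signal(fi, FEATURE_FS, 2.0, overlap), axis=1)
        cols[f"inst_freq_b{b + 1}"] = expand_to_samples(fw, n64, FEATURE_FS, 2.0, overlap)

    values = np.column_stack([cols[s.column] for s in specs])
    if values.shape[0] != n64:
        raise AssertionError("feature grid length mismatch")
    return FeatureMatrix(values, specs)


def transform_and_zscore(
    fm: FeatureMatrix,
    train_stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[FeatureMatrix, tuple[np.ndarray, np.ndarray]]:
    """Natural-log transform heavy-tailed features, then z-score all columns.

    Log-transformed columns (energy, envelope and spectral-power features)
    are floored at 1e-12 before the log.  If ``train_stats`` (mean, sd) is
    given those parameters are applied; otherwise they are estimated from
    ``fm`` and returned for later reuse on test data.
    """
    v = fm.values.copy()
    for j, spec in enumerate(fm.specs):
        if spec.log_transformed:
            v[:, j] = np.log(np.maximum(v[:, j], LOG_FLOOR))
    if train_stats is None:
        mean = v.mean(axis=0)
        sd = v.std(axis=0)
        zero = sd == 0
        if zero.any():
            bad = [fm.specs[j].column for j in np.flatnonzero(zero)]
            raise ValueError(f"zero variance in feature(s): {bad}")
    else:
        mean, sd = train_stats
    z = (v - mean) / sd
    return FeatureMatrix(z, fm.specs, fm.fs), (mean, sd)


def welch_psd(x: np.ndarray, fs: float, window_s: float = 2.0):
    """Welch PSD with a Hamming window (cohort-spectrum utility)."""
    nper = int(round(window_s * fs))
    return sps.welch(np.asarray(x, dtype=float), fs=fs, window="hamming",
                     nperseg=nper, noverlap=nper // 2)
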