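"""Literal loop-over-definition reference implementations.

Each function here evaluates a feature definition directly — explicit DFT
sums, per-sample loops, closed-form OLS — independently of the vectorised
code paths in the package, so the two can be compared on random windows.
"""

import numpy as np


def dft(x):
    """Explicit O(N²) discrete Fourier transform."""
    x = np.asarray(x, dtype=float)
    n = x.size
    k = np.arange(n)
    return np.array([np.sum(x * np.exp(-2j * np.pi * kk * k / n)) for kk in range(n)])


def hilbert_oracle(x):
    """Discrete Hilbert transform via IDFT{-j sgn(N/2 - k) sgn(k) X(k)}."""
    x = np.asarray(x, dtype=float)
    n = x.size
    X = dft(x)
    weights = np.array([-1j * np.sign(n / 2 - k) * np.sign(k) for k in range(n)])
    H = weights * X
    m = np.arange(n)
    return np.array(
        [np.real(np.sum(H * np.exp(2j * np.pi * k * m / n)) / n) for k in range(n)]
    )


def envelope_oracle(x):
    h = hilbert_oracle(x)
    return np.array([abs(complex(xi, hi)) ** 2 for xi, hi in zip(x, h)])


def relative_power_oracle(x, fs, band, total_band=(0.5, 30)):
    X = dft(x)
    n = len(x)
    num = den = 0.0
    for k in range(n // 2):
        f = k * fs / n
        p = abs(X[k]) ** 2
        if band[0] <= f < band[1]:
            num += p
        if total_band[0] <= f < total_band[1]:
            den += p
    return num / den


def loglog_fit_oracle(x, fs, band, floor=1e-12):
    X = dft(x)
    n = len(x)
    pts = []
    for k in range(n // 2):
        f = k * fs / n
        if band[0] <= f < band[1]:
            pts.append((np.log(f), np.log(max(abs(X[k]) ** 2, floor))))
    F = np.array([p[0] for p in pts])
    Y = np.array([p[1] for p in pts])
    m = len(pts)
    slope = (m * np.sum(F * Y) - F.sum() * Y.sum()) / (m * np.sum(F**2) - F.sum() ** 2)
    c1 = (Y.sum() - slope * F.sum()) / m
    ss_res = np.sum((Y - (c1 + slope * F)) ** 2)
    ss_tot = np.sum((Y - Y.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return slope, r2


def mean_frequency_oracle(x, fs):
    X = dft(x)
    n = len(x)
    z = 0j
    for k in range(n // 2):
        z += abs(X[k]) ** 2 * np.exp(1j * 4 * np.pi * k / n)
    return fs / (4 * np.pi) * (np.angle(z) % (2 * np.pi))


def instantaneous_frequency_oracle(x, fs):
    h = hilbert_oracle(x)
    phi = np.array([np.angle(complex(xi, hi)) for xi, hi in zip(x, h)])
    n = len(x)
    f = np.empty(n)
    for i in range(1, n - 1):
        f[i] = fs / (4 * np.pi) * ((phi[i + 1] - phi[i - 1]) % (2 * np.pi))
    f[0], f[-1] = f[1], f[-2]
    return f


def higuchi_oracle(x, k_max):
    x = np.asarray(x, dtype=float)
    n = len(x)
    logk, logL = [], []
    for k in range(1, k_max + 1):
        Lm = []
        for m in range(1, k + 1):
            n_i = (n - m) // k
            if n_i < 1:
                continue
            s = 0.0
            for i in range(1, n_i + 1):
                # 1-based series indexing: x[m + ik] -> 0-based x[m - 1 + ik]
                s += abs(x[m - 1 + i * k] - x[m - 1 + (i - 1) * k])
            Lm.append((n - 1) / (n_i * k * k) * s)
        logk.append(np.log(k))
        logL.append(np.log(np.mean(Lm)))
    logk, logL = np.array(logk), np.array(logL)
    m = len(logk)
    slope = (m * np.sum(logk * logL) - logk.sum() * logL.sum()) / (
        m * np.sum(logk**2) - logk.sum() ** 2
    )
    return -slope


def nleo_oracle(x):
    x = np.asarray(x, dtype=float)
    out = []
    for n in range(3, len(x)):
        out.append(abs(x[n - 1] * x[n - 2] - x[n] * x[n - 3]))
    out = np.array(out)
    return np.concatenate((np.full(3, out[0]), out))


def line_length_oracle(x):
    x = np.asarray(x, dtype=float)
    return sum(abs(x[n + 1] - x[n]) for n in range(len(x) - 1))


def edo_oracle(x, printed_sign=False):
    x = np.asarray(x, dtype=float)
    h = hilbert_oracle(x)
    s = 1.0 if printed_sign else -1.0
    out = []
    for n in range(1, len(x) - 1):
        quad = 0.25 * (
            x[n + 1] ** 2 + x[n - 1] ** 2 + h[n + 1] ** 2 + h[n - 1] ** 2
        )
        cross = 0.5 * (x[n + 1] * x[n - 1] + h[n + 1] * h[n - 1])
        out.append(quad + s * cross)
    out = np.array(out)
    return np.concatenate(([out[0]], out, [out[-1]]))


def auc_pair_count_oracle(scores, labels):
    """AUC by exhaustive concordant/discordant pair counting (ties = 1/2)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = conc = 0.0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                conc += 1
            elif p == q:
                conc += 0.5
    return conc / total
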