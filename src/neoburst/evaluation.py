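"""Detection metrics, inter-rater agreement, and inter-burst-interval summaries.

Sample-based metrics (AUC, sensitivity/specificity, Cohen's κ) are computed
over the samples with a defined reference label; UNDEFINED (non-consensus)
samples are excluded throughout.  The event-based assessment counts a
reference event as detected when strictly more than 75% of its duration is
covered, independent of how fragmented the detection is.  Inter-burst
interval (IBI) statistics — median IBI, maximum IBI and the
burst-to-inter-burst ratio — are the maturational summary measures derived
from the binary output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as spstats
from sklearn.metrics import roc_auc_score

from .core import BURST, INTER_BURST, UNDEFINED, Annotation


def _aligned_defined(a1: Annotation, a2: Annotation) -> tuple[np.ndarray, np.ndarray]:
    if a1.fs != a2.fs or a1.labels.size != a2.labels.size:
        raise ValueError("annotations must share sampling rate and length")
    keep = (a1.labels != UNDEFINED) & (a2.labels != UNDEFINED)
    return a1.labels[keep], a2.labels[keep]


# ---------------------------------------------------------------------------
# Sample-based metrics
# ---------------------------------------------------------------------------

def auc_samplewise(D: np.ndarray, reference: Annotation) -> float:
    """Rank-based AUC of the continuous output, bursts as signal-of-interest.

    Ties are handled by the midrank convention; invariant under any
    strictly monotone transform of D.
    """
    D = np.asarray(D, dtype=float)
    keep = reference.labels != UNDEFINED
    y = reference.labels[keep] == BURST
    if y.all() or not y.any():
        warnings.warn("single-class reference: AUC undefined")
        return float("nan")
    return float(roc_auc_score(y, D[keep]))


def sens_spec_time(detected: Annotation, reference: Annotation) -> tuple[float, float]:
    """Sample-by-sample sensitivity and specificity in percent."""
    ref, det = _paired(reference, detected)
    pos, neg = ref == BURST, ref == INTER_BURST
    if not pos.any() or not neg.any():
        warnings.warn("a reference class is empty; sensitivity/specificity undefined")
    sens = 100.0 * np.mean(det[pos] == BURST) if pos.any() else float("nan")
    spec = 100.0 * np.mean(det[neg] == INTER_BURST) if neg.any() else float("nan")
    return float(sens), float(spec)


def _paired(reference: Annotation, detected: Annotation) -> tuple[np.ndarray, np.ndarray]:
    if reference.fs != detected.fs or reference.labels.size != detected.labels.size:
        raise ValueError("annotations must share sampling rate and length")
    keep = reference.labels != UNDEFINED
    return reference.labels[keep], detected.labels[keep]


# ---------------------------------------------------------------------------
# Event-based metrics
# ---------------------------------------------------------------------------

def sens_spec_event(
    detected: Annotation, reference: Annotation, coverage: float = 0.75
) -> tuple[float, float]:
    """Event-based sensitivity and specificity in percent.

    A reference event counts as detected when strictly more than
    ``coverage`` of its samples carry the same label in the detection;
    coverage pools over possibly fragmented detections.  Sensitivity is
    over reference burst events, specificity over inter-burst events.
    """
    if reference.fs != detected.fs or reference.labels.size != detected.labels.size:
        raise ValueError("annotations must share sampling rate and length")
    out = []
    for lab in (BURST, INTER_BURST):
        events = [(s, e) for s, e, l in reference.segments() if l == lab]
        if not events:
            warnings.warn(f"no reference events of class {lab}")
            out.append(float("nan"))
            continue
        hits = sum(
            1
            for s, e in events
            if np.mean(detected.labels[s:e] == lab) > coverage
        )
        out.append(100.0 * hits / len(events))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Agreement
# ---------------------------------------------------------------------------

def cohens_kappa(a1: Annotation, a2: Annotation) -> tuple[float, float, float]:
    """Cohen's κ with bias and prevalence indices from the 2×2 table.

    With a, d the agreed burst / inter-burst counts and b, c the
    disagreements: bias = |b − c| / n (difference in the raters' burst
    proportions) and prevalence = |a − d| / n (imbalance of agreed bursts
    vs inter-bursts); both contextualise the magnitude of κ.
    """
    l1, l2 = _aligned_defined(a1, a2)
    if l1.size == 0:
        raise ValueError("no jointly defined samples")
    a = int(np.sum((l1 == BURST) & (l2 == BURST)))
    d = int(np.sum((l1 == INTER_BURST) & (l2 == INTER_BURST)))
    b = int(np.sum((l1 == BURST) & (l2 == INTER_BURST)))
    c = int(np.sum((l1 == INTER_BURST) & (l2 == BURST)))
    n = a + b + c + d
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    if pe == 1:
        warnings.warn("degenerate table: chance agreement is 1, kappa undefined")
        kappa = float("nan")
    else:
        kappa = (po - pe) / (1 - pe)
    return float(kappa), float(abs(b - c) / n), float(abs(a - d) / n)


def auc_between_annotations(a1: Annotation, a2: Annotation) -> float:
    """Agreement AUC between two binary annotations.

    Convention: each annotation in turn is treated as a 0/1 score against
    the other as reference, and the two AUCs are averaged.
    """
    u = auc_samplewise((a1.labels == BURST).astype(float), a2)
    v = auc_samplewise((a2.labels == BURST).astype(float), a1)
    return float(np.mean([u, v]))


# ---------------------------------------------------------------------------
# IBI summaries
# ---------------------------------------------------------------------------

def ibi_summary(a: Annotation) -> tuple[float, float, float]:
    """(median IBI s, max IBI s, burst-to-inter-burst ratio %).

    IBIs are durations of complete inter-burst segments; segments touching
    the record edges are truncated and excluded from the duration
    statistics but still count towards the time ratio.  The ratio is the
    percentage of defined time labelled as burst.
    """
    segs = a.segments()
    ibis = [
        (e - s) / a.fs
        for i, (s, e, lab) in enumerate(segs)
        if lab == INTER_BURST and 0 < i < len(segs) - 1
    ]
    n_burst = int(np.sum(a.labels == BURST))
    n_inter = int(np.sum(a.labels == INTER_BURST))
    if n_burst + n_inter == 0:
        raise ValueError("annotation has no defined samples")
    ratio = 100.0 * n_burst / (n_burst + n_inter)
    if not ibis:
        warnings.warn("no complete inter-burst segments: IBI statistics undefined")
        return float("nan"), float("nan"), float(ratio)
    return float(np.median(ibis)), float(max(ibis)), float(ratio)


# ---------------------------------------------------------------------------
# Paired statistics
# ---------------------------------------------------------------------------

def bootstrap_ci(
    values: np.ndarray,
    stat=np.median,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap 95% CI of a statistic, seeded."""
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    stats = np.array(
        [stat(values[rng.integers(0, values.size, values.size)]) for _ in range(n_boot)]
    )
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(lo), float(hi)


def paired_comparison(
    x: np.ndarray, y: np.ndarray, n_boot: int = 1000, seed: int = 0
) -> tuple[float, tuple[float, float], float]:
    """Paired comparison of per-record values.

    Returns (median difference x − y, bootstrap 95% CI, Wilcoxon
    signed-rank p).  All-zero differences give p = 1 by convention.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need equal-length samples of at least 5 pairs")
    d = x - y
    if np.all(d == 0):
        warnings.warn("all paired differences are zero")
        p = 1.0
    else:
        p = float(spstats.wilcoxon(x, y).pvalue)
    ci = bootstrap_ci(d, np.median, n_boot, seed)
    return float(np.median(d)), ci, p


# ---------------------------------------------------------------------------
# Report container
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-record detection evaluation against a reference annotation."""

    auc: float
    sens_time: float
    spec_time: float
    sens_event: float
    spec_event: float
    kappa: float
    bias: float
    prevalence: float
    ibi_median_s: float
    ibi_max_s: float
    burst_ratio_pct: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_detection(
    D: np.ndarray | None, detected: Annotation, reference: Annotation
) -> EvaluationReport:
    """Full per-record report; pass ``D`` for the continuous-output AUC
    (``None`` falls back to the binary detection as the score)."""
    score = (detected.labels == BURST).astype(float) if D is None else D
    sens_t, spec_t = sens_spec_time(detected, reference)
    sens_e, spec_e = sens_spec_event(detected, reference)
    kappa, bias, prev = cohens_kappa(detected, reference)
    med, mx, ratio = ibi_summary(detected)
    return EvaluationReport(
        auc=auc_samplewise(score, reference),
        sens_time=sens_t,
        spec_time=spec_t,
        sens_event=sens_e,
        spec_event=spec_e,
        kappa=kappa,
        bias=bias,
        prevalence=prev,
        ibi_median_s=med,
        ibi_max_s=mx,
        burst_ratio_pct=ratio,
    )
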