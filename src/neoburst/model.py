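"""Detector training: feature selection, linear SVM, and post-processing.

The detector fuses the 26 per-sample features with a linear support vector
machine, D[x(n)] = Σ_p w_p x_p(n) + b, trained on consensus-labelled
samples (burst = +1, inter-burst = −1).  Feature selection runs in two
stages: an mRMR (maximum-relevance minimum-redundancy) mutual-information
filter, then a backwards-elimination wrapper scored by inner
leave-one-record-out AUC.  The continuous output is thresholded (static
T = 0 or per-record adaptive T = mean D) and cleaned by minimum-duration
limits taken from the 2.5th percentile of annotated segment durations.

Two estimators expose this with the scikit-learn fit/predict contract:

* :class:`BurstClassifier` — operates on feature rows (n_samples, n_features);
  composes with sklearn model selection.
* :class:`BurstDetector` — operates on raw EEG channels; wraps feature
  extraction, the classifier, thresholding and duration limits, and
  serialises to a versioned JSON document.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import mutual_info_score, roc_auc_score
from sklearn.svm import LinearSVC

from .core import BURST, INTER_BURST, UNDEFINED, Annotation
from .features import (
    FEATURE_FS,
    FeatureMatrix,
    FeatureSpec,
    LOG_FLOOR,
    default_feature_set,
    extract_features,
)

FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# Training-data preparation
# ---------------------------------------------------------------------------

def subsample_training(
    X: np.ndarray, y: np.ndarray, step: int = 500, groups: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministically keep every ``step``-th defined-label row.

    Returns (X_sub, y_sub, kept_indices).  Only a small fraction of the
    per-sample feature stream is needed for training: neighbouring samples
    are heavily correlated, and thinning keeps the class distributions
    representative at a fraction of the cost.  With ``groups`` (record
    ids) the step is applied within each record, so the retained set does
    not depend on the order records are concatenated in.
    """
    X, y = np.asarray(X), np.asarray(y)
    if groups is None:
        idx = np.arange(y.size)[::step]
    else:
        groups = np.asarray(groups)
        seen: list[np.ndarray] = []
        order = dict.fromkeys(groups.tolist())  # first-occurrence order
        for g in order:
            seen.append(np.flatnonzero(groups == g)[::step])
        idx = np.concatenate(seen)
    ys = y[idx]
    if np.unique(ys).size < 2:
        raise ValueError(
            f"subsampling step {step} left a single class; use a smaller step"
        )
    return X[idx], ys, idx


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def mrmr_filter(
    X: np.ndarray, y: np.ndarray, n_keep: int, n_bins: int = 10
) -> list[int]:
    """Greedy mRMR ranking (difference form) of feature columns.

    Features are discretised by equal-frequency binning; the first pick
    maximises mutual information with the labels, subsequent picks maximise
    relevance minus mean redundancy against the already-selected set.
    """
    X, y = np.asarray(X), np.asarray(y)
    n_feat = X.shape[1]
    if np.unique(y).size < 2:
        raise ValueError("mRMR needs at least two classes")
    if n_keep > n_feat:
        warnings.warn(f"n_keep={n_keep} clipped to {n_feat} features")
        n_keep = n_feat
    disc = np.column_stack([_equal_frequency_bins(X[:, j], n_bins) for j in range(n_feat)])
    relevance = np.array([mutual_info_score(y, disc[:, j]) for j in range(n_feat)])
    selected: list[int] = [int(np.argmax(relevance))]
    red = np.zeros(n_feat)
    while len(selected) < n_keep:
        last = selected[-1]
        for j in range(n_feat):
            if j not in selected:
                red[j] += mutual_info_score(disc[:, last], disc[:, j])
        score = relevance - red / len(selected)
        score[selected] = -np.inf
        selected.append(int(np.argmax(score)))
    return selected


def _make_svm(C: float, tol: float) -> LinearSVC:
    # primal squared-hinge liblinear: deterministic and fast on thinned data
    return LinearSVC(C=C, tol=tol, dual=False, class_weight="balanced")


def train_svm(
    X: np.ndarray, y: np.ndarray, C: float = 1.0, tol: float = 1e-4
) -> tuple[np.ndarray, float]:
    """Fit the linear SVM; returns (weights, bias) with positive scores
    predicting bursts."""
    X, y = np.asarray(X, dtype=float), np.asarray(y)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    if np.unique(y).size < 2:
        raise ValueError("need both classes to train")
    clf = _make_svm(C, tol).fit(X, (y == BURST).astype(int))
    return clf.coef_.ravel().copy(), float(clf.intercept_[0])


def _inner_folds(groups: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    folds = []
    for g in np.unique(groups):
        test = groups == g
        folds.append((np.flatnonzero(~test), np.flatnonzero(test)))
    return folds


def _subset_auc(
    X: np.ndarray,
    y: np.ndarray,
    subset: list[int],
    folds: list[tuple[np.ndarray, np.ndarray]],
    C: float,
    tol: float,
) -> float:
    aucs = []
    cols = np.asarray(subset)
    for train, test in folds:
        ytr, yte = y[train], y[test]
        if np.unique(ytr).size < 2 or np.unique(yte).size < 2:
            warnings.warn("degenerate inner fold (single class); skipping")
            continue
        clf = _make_svm(C, tol).fit(X[np.ix_(train, cols)], ytr)
        d = clf.decision_function(X[np.ix_(test, cols)])
        aucs.append(roc_auc_score(yte, d))
    return float(np.mean(aucs)) if aucs else float("nan")


def backwards_elimination(
    X: np.ndarray,
    y: np.ndarray,
    candidates: list[int],
    groups: np.ndarray,
    C: float = 1.0,
    tol: float = 1e-4,
) -> list[int]:
    """Wrapper stage: iteratively drop the feature whose removal maximises
    inner leave-one-record-out AUC; return the best subset along the path.

    Ties prefer the smaller subset, then lexicographic feature order.
    """
    folds = _inner_folds(np.asarray(groups))
    current = sorted(candidates)
    path = [(_subset_auc(X, y, current, folds, C, tol), list(current))]
    while len(current) > 1:
        best_auc, best_removal = -np.inf, None
        for f in current:
            trial = [c for c in current if c != f]
            auc = _subset_auc(X, y, trial, folds, C, tol)
            if auc > best_auc:
                best_auc, best_removal = auc, f
        current = [c for c in current if c != best_removal]
        path.append((best_auc, list(current)))
    # best subset: max AUC, ties -> fewer features, then lexicographic
    path.sort(key=lambda t: (-t[0], len(t[1]), tuple(t[1])))
    return path[0][1]


# ---------------------------------------------------------------------------
# Post-processing
# ---------------------------------------------------------------------------

def estimate_duration_limits(
    annotations: list[Annotation], percentile: float = 2.5
) -> tuple[float, float]:
    """Minimum plausible burst / inter-burst durations (seconds).

    Pools complete (non-record-edge) annotated segment durations per class
    and takes the given percentile (linear interpolation).  Edge segments
    are truncated, so their true duration is unknown.
    """
    durations: dict[int, list[float]] = {BURST: [], INTER_BURST: []}
    for a in annotations:
        segs = a.segments()
        for i, (s, e, lab) in enumerate(segs):
            if lab in durations and 0 < i < len(segs) - 1:
                durations[lab].append((e - s) / a.fs)
    for lab, name in ((BURST, "burst"), (INTER_BURST, "inter-burst")):
        if not durations[lab]:
            raise ValueError(f"no complete {name} segments in the annotations")
    return (
        float(np.percentile(durations[BURST], percentile)),
        float(np.percentile(durations[INTER_BURST], percentile)),
    )


def apply_threshold(D: np.ndarray, mode: str = "static") -> np.ndarray:
    """Binarise the SVM output: BURST where D > T.

    ``static`` uses T = 0; ``adaptive`` uses the per-record mean of D, an
    infant-dependent operating point.
    """
    D = np.asarray(D, dtype=float)
    if not np.isfinite(D).all():
        raise ValueError("non-finite decision values")
    if mode == "static":
        t = 0.0
    elif mode == "adaptive":
        t = float(D.mean())
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    return np.where(D > t, BURST, INTER_BURST).astype(np.int8)


def enforce_duration_limits(
    labels: np.ndarray, fs: float, min_burst_s: float, min_inter_burst_s: float
) -> np.ndarray:
    """Remove implausibly short segments by relabelling them to the
    flanking class.

    Processed shortest-segment-first, bursts before inter-bursts on ties.
    Segments touching the record edges are exempt (they are truncated, not
    complete).  Idempotent.
    """
    lab = np.asarray(labels, dtype=np.int8).copy()
    limits = {BURST: min_burst_s, INTER_BURST: min_inter_burst_s}
    while True:
        a = Annotation(lab, fs)
        segs = a.segments()
        short = [
            (s, e, l)
            for i, (s, e, l) in enumerate(segs)
            if l in limits and 0 < i < len(segs) - 1 and (e - s) / fs < limits[l]
        ]
        if not short:
            return lab
        s, e, l = min(short, key=lambda t: (t[1] - t[0], 0 if t[2] == BURST else 1))
        lab[s:e] = BURST if l == INTER_BURST else INTER_BURST


# ---------------------------------------------------------------------------
# Feature-row classifier (sklearn estimator)
# ---------------------------------------------------------------------------

class BurstClassifier(ClassifierMixin, BaseEstimator):
    """Linear-SVM burst classifier on per-sample feature rows.

    Expects log-transformed (but not yet z-scored) feature values; fitting
    estimates per-feature z-score parameters, thins the training rows,
    runs mRMR + backwards-elimination feature selection, and trains the
    linear SVM on the selected columns.

    Parameters
    ----------
    n_filter : size of the mRMR filter-stage shortlist.
    C, tol : SVM regularisation and solver tolerance.
    n_bins : equal-frequency bins for mutual-information estimation.
    subsample_step : keep every n-th training row.
    wrapper : run the backwards-elimination wrapper (else keep the full
        mRMR shortlist).

    Attributes (after fit)
    ----------------------
    mean_, scale_ : z-score parameters over all features.
    ranking_ : mRMR shortlist (column indices).
    selected_ : final selected column indices.
    coef_, intercept_ : SVM weights over ``selected_`` and bias.
    """

    def __init__(
        self,
        n_filter: int = 16,
        C: float = 1.0,
        tol: float = 1e-4,
        n_bins: int = 10,
        subsample_step: int = 500,
        wrapper: bool = True,
    ):
        self.n_filter = n_filter
        self.C = C
        self.tol = tol
        self.n_bins = n_bins
        self.subsample_step = subsample_step
        self.wrapper = wrapper

    def fit(self, X, y, groups=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be (n_samples, n_features) aligned with y")
        if not np.isfinite(X).all():
            raise ValueError("non-finite feature values")
        self.classes_ = np.array([INTER_BURST, BURST])

        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        if (sd == 0).any():
            raise ValueError(
                f"zero variance in feature column(s) {np.flatnonzero(sd == 0).tolist()}"
            )
        self.scale_ = sd
        Z = (X - self.mean_) / self.scale_

        Zs, ys, kept = subsample_training(Z, y, self.subsample_step, groups)
        gs = None if groups is None else np.asarray(groups)[kept]

        self.ranking_ = mrmr_filter(Zs, ys, self.n_filter, self.n_bins)
        if self.wrapper:
            if gs is None:
                # no record structure: contiguous 5-fold pseudo-records
                gs = np.minimum(np.arange(ys.size) * 5 // max(ys.size, 1), 4)
            self.selected_ = backwards_elimination(
                Zs, ys, self.ranking_, gs, self.C, self.tol
            )
        else:
            self.selected_ = sorted(self.ranking_)

        w, b = train_svm(Zs[:, self.selected_], ys, self.C, self.tol)
        self.coef_ = w
        self.intercept_ = b
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Z = (X - self.mean_) / self.scale_
        return Z[:, self.selected_] @ self.coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_function(X) > 0, BURST, INTER_BURST)


# ---------------------------------------------------------------------------
# Record-level detector
# ---------------------------------------------------------------------------

def _log_transform(fm: FeatureMatrix) -> np.ndarray:
    v = fm.values.copy()
    for j, spec in enumerate(fm.specs):
        if spec.log_transformed:
            v[:, j] = np.log(np.maximum(v[:, j], LOG_FLOOR))
    return v


class BurstDetector(BaseEstimator):
    """End-to-end burst detector on raw EEG channels.

    ``fit`` takes single-channel µV signals with per-sample annotations;
    ``detect`` segments a new channel into bursts and inter-bursts.  The
    fitted state (selected features, z-score parameters, SVM weights,
    threshold mode, duration limits) serialises to JSON.
    """

    def __init__(
        self,
        threshold_mode: str = "static",
        n_filter: int = 16,
        C: float = 1.0,
        tol: float = 1e-4,
        n_bins: int = 10,
        subsample_step: int = 500,
        wrapper: bool = True,
        limit_percentile: float = 2.5,
        k_max: int = 8,
    ):
        self.threshold_mode = threshold_mode
        self.n_filter = n_filter
        self.C = C
        self.tol = tol
        self.n_bins = n_bins
        self.subsample_step = subsample_step
        self.wrapper = wrapper
        self.limit_percentile = limit_percentile
        self.k_max = k_max

    # -- training ----------------------------------------------------------

    def fit(self, signals: list[np.ndarray], annotations: list[Annotation], fs: float):
        """Train on single-channel signals with aligned annotations.

        Annotations are resampled to the 64 Hz feature grid; UNDEFINED
        (non-consensus) samples are excluded from training.
        """
        if len(signals) != len(annotations):
            raise ValueError("one annotation per signal required")
        mats = [
            extract_features(np.asarray(x, dtype=float), fs, k_max=self.k_max)
            for x in signals
        ]
        self.feature_specs_ = mats[0].specs
        rows, labels, groups = [], [], []
        for rid, (fm, ann) in enumerate(zip(mats, annotations)):
            v = _log_transform(fm)
            lab = ann.resample(FEATURE_FS).labels[: v.shape[0]]
            keep = lab != UNDEFINED
            rows.append(v[keep])
            labels.append(lab[keep])
            groups.append(np.full(int(keep.sum()), rid))
        X = np.vstack(rows)
        y = np.concatenate(labels)
        g = np.concatenate(groups)

        self.classifier_ = BurstClassifier(
            n_filter=self.n_filter,
            C=self.C,
            tol=self.tol,
            n_bins=self.n_bins,
            subsample_step=self.subsample_step,
            wrapper=self.wrapper,
        ).fit(X, y, groups=g)
        self.min_burst_s_, self.min_inter_burst_s_ = estimate_duration_limits(
            annotations, self.limit_percentile
        )
        return self

    # -- inference ---------------------------------------------------------

    def decision_function(self, x: np.ndarray, fs: float) -> np.ndarray:
        """Continuous SVM output D[x(n)] on the 64 Hz grid for one channel."""
        fm = extract_features(np.asarray(x, dtype=float), fs, k_max=self.k_max)
        return self.classifier_.decision_function(_log_transform(fm))

    def detect(
        self, x: np.ndarray, fs: float, threshold_mode: str | None = None
    ) -> Annotation:
        """Segment one channel into bursts / inter-bursts at 64 Hz."""
        D = self.decision_function(x, fs)
        binary = apply_threshold(D, threshold_mode or self.threshold_mode)
        cleaned = enforce_duration_limits(
            binary, FEATURE_FS, self.min_burst_s_, self.min_inter_burst_s_
        )
        return Annotation(cleaned, FEATURE_FS)

    def detect_record(self, record, threshold_mode: str | None = None) -> list[Annotation]:
        """Channel-independent detection over all channels of an EEGRecord."""
        return [
            self.detect(record.samples[c], record.fs, threshold_mode)
            for c in range(record.n_channels)
        ]

    # -- persistence -------------------------------------------------------

    def to_json(self) -> str:
        clf = self.classifier_
        doc = {
            "format_version": FORMAT_VERSION,
            "params": self.get_params(),
            "feature_names": [s.column for s in self.feature_specs_],
            "selected": [int(i) for i in clf.selected_],
            "zscore_mean": clf.mean_.tolist(),
            "zscore_sd": clf.scale_.tolist(),
            "weights": clf.coef_.tolist(),
            "bias": clf.intercept_,
            "min_burst_s": self.min_burst_s_,
            "min_inter_burst_s": self.min_inter_burst_s_,
        }
        return json.dumps(doc, indent=1)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "BurstDetector":
        doc = json.loads(text)
        if doc.get("format_version") != FORMAT_VERSION:
            raise ValueError(f"unsupported detector format {doc.get('format_version')}")
        det = cls(**doc["params"])
        det.feature_specs_ = default_feature_set()
        if [s.column for s in det.feature_specs_] != doc["feature_names"]:
            raise ValueError("feature set mismatch in detector document")
        clf = BurstClassifier(
            n_filter=det.n_filter, C=det.C, tol=det.tol, n_bins=det.n_bins,
            subsample_step=det.subsample_step, wrapper=det.wrapper,
        )
        clf.classes_ = np.array([INTER_BURST, BURST])
        clf.mean_ = np.asarray(doc["zscore_mean"], dtype=float)
        clf.scale_ = np.asarray(doc["zscore_sd"], dtype=float)
        clf.selected_ = [int(i) for i in doc["selected"]]
        clf.ranking_ = list(clf.selected_)
        clf.coef_ = np.asarray(doc["weights"], dtype=float)
        clf.intercept_ = float(doc["bias"])
        det.classifier_ = clf
        det.min_burst_s_ = float(doc["min_burst_s"])
        det.min_inter_burst_s_ = float(doc["min_inter_burst_s"])
        return det

    @classmethod
    def load(cls, path: str | Path) -> "BurstDetector":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    record_id: int
    selected_features: list[str]
    auc: float
    sensitivity: float
    specificity: float


@dataclass
class CVResult:
    """Leave-one-record-out results with bootstrap aggregate summaries."""

    folds: list[FoldResult]
    aggregate: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def values(self, metric: str) -> np.ndarray:
        return np.array([getattr(f, metric) for f in self.folds])


def _bootstrap_ci(
    values: np.ndarray, rng: np.random.Generator, n_boot: int = 1000
) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    stats = np.median(
        values[rng.integers(0, values.size, size=(n_boot, values.size))], axis=1
    )
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(lo), float(hi)


def nested_cv(
    signals: list[np.ndarray],
    annotations: list[Annotation],
    fs: float,
    detector_params: dict | None = None,
    threshold_mode: str = "static",
    n_boot: int = 1000,
    seed: int = 0,
    feature_matrices: list[FeatureMatrix] | None = None,
) -> CVResult:
    """Nested leave-one-record-out cross-validation of the full pipeline.

    For each outer fold everything — z-score parameters, mRMR + wrapper
    feature selection (inner leave-one-record-out), SVM weights and
    duration limits — is fitted on the training records only; the held-out
    record is scored on its defined (consensus) samples.  Aggregates are
    medians with percentile-bootstrap 95% CIs.

    Pass ``feature_matrices`` to reuse pre-extracted features.
    """
    from .evaluation import auc_samplewise, sens_spec_time

    n_in = len(feature_matrices) if feature_matrices is not None else len(signals)
    if n_in < 3:
        raise ValueError("nested CV needs at least 3 records")
    params = dict(detector_params or {})
    if feature_matrices is None:
        feature_matrices = [
            extract_features(np.asarray(x, dtype=float), fs,
                             k_max=params.get("k_max", 8))
            for x in signals
        ]
    logged = [_log_transform(fm) for fm in feature_matrices]
    labs64 = [
        a.resample(FEATURE_FS).labels[: v.shape[0]]
        for a, v in zip(annotations, logged)
    ]

    n_rec = len(logged)
    usable = [i for i in range(n_rec) if np.any(labs64[i] != UNDEFINED)]
    if len(usable) < n_rec:
        warnings.warn(f"excluding {n_rec - len(usable)} record(s) with no defined labels")

    folds: list[FoldResult] = []
    for i in usable:
        train_ids = [j for j in usable if j != i]
        rows, ys, gs = [], [], []
        for j in train_ids:
            keep = labs64[j] != UNDEFINED
            rows.append(logged[j][keep])
            ys.append(labs64[j][keep])
            gs.append(np.full(int(keep.sum()), j))
        clf = BurstClassifier(
            n_filter=params.get("n_filter", 16),
            C=params.get("C", 1.0),
            tol=params.get("tol", 1e-4),
            n_bins=params.get("n_bins", 10),
            subsample_step=params.get("subsample_step", 500),
            wrapper=params.get("wrapper", True),
        ).fit(np.vstack(rows), np.concatenate(ys), groups=np.concatenate(gs))
        mb, mi = estimate_duration_limits(
            [annotations[j] for j in train_ids], params.get("limit_percentile", 2.5)
        )

        D = clf.decision_function(logged[i])
        ref = Annotation(labs64[i], FEATURE_FS)
        auc = auc_samplewise(D, ref)
        binary = enforce_duration_limits(
            apply_threshold(D, threshold_mode), FEATURE_FS, mb, mi
        )
        sens, spec = sens_spec_time(Annotation(binary, FEATURE_FS), ref)
        names = [feature_matrices[i].specs[k].column for k in clf.selected_]
        folds.append(FoldResult(i, names, auc, sens, spec))

    rng = np.random.default_rng(seed)
    result = CVResult(folds)
    for metric in ("auc", "sensitivity", "specificity"):
        vals = result.values(metric)
        vals = vals[np.isfinite(vals)]
        lo, hi = _bootstrap_ci(vals, rng, n_boot)
        result.aggregate[metric] = (float(np.median(vals)), lo, hi)
    return result
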