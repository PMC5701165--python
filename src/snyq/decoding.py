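"""Six-way stimulus classification from EEG, per time point and from
15 Hz SSVEP amplitudes, per electrode array.

The classifier is the study's: per cross-validation fold, z-score each
feature using training statistics, fit PCA on the training data keeping
components up to a cumulative-variance criterion, project the test data
with the training weights, fit linear maximum-margin (SVM) classifiers for
every condition pair, and aggregate one-vs-one votes (ties broken by the
summed signed decision values).  Folds are stratified by condition and
seeded.  Chance for six balanced classes is 100/6 ~ 16.66 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .preprocess import PseudotrialSet, average_reference

__all__ = [
    "CHANCE_PCT",
    "DecodingConfig",
    "DecodingTrace",
    "SSVEPFeatures",
    "decode_features",
    "decode_timepoint",
    "decode_timecourse",
    "ssvep_features",
    "pca_sweep_decode",
    "confusion_by_condition",
]

CHANCE_PCT = 100.0 / 6.0


@dataclass
class DecodingConfig:
    """Cross-validation and feature-reduction settings."""

    n_folds: int = 10
    pca_variance: float = 0.99  # time-domain decoding criterion
    pca_variance_levels: tuple = (0.1, 0.2, 0.3, 0.4, 0.5,
                                  0.6, 0.7, 0.8, 0.9, 0.99)
    svm_c: float = 1.0
    rereference: bool = True
    peak_window_ms: tuple = (80.0, 140.0)
    peak_average_ms: float = 10.0
    seed: int = 0


@dataclass
class DecodingTrace:
    """Time-resolved decoding accuracy for one subject and array."""

    time_ms: np.ndarray
    accuracy: np.ndarray  # % correct per time point
    array_name: str = ""
    chance: float = CHANCE_PCT
    peak_time_ms: float = np.nan
    peak_accuracy: float = np.nan
    confusion: np.ndarray = None  # 6x6 counts at the peak time point

    def __post_init__(self):
        a = np.asarray(self.accuracy, dtype=float)
        if np.any((a < 0) | (a > 100)):
            raise ValueError("accuracies must lie in [0, 100]")


@dataclass
class SSVEPFeatures:
    """Per-pseudotrial, per-electrode 15 Hz amplitude."""

    amplitude: np.ndarray  # pseudotrials x electrodes
    labels: np.ndarray
    freq_hz: float = 15.0

    def __post_init__(self):
        if np.any(self.amplitude < 0):
            raise ValueError("amplitudes must be nonnegative")


def _ovo_predict(dec: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Vote aggregation over one-vs-one decision values.

    ``dec`` has one column per class pair in sklearn's (i, j), i<j order; a
    positive value votes for class i.  Ties in vote counts are broken by
    the summed signed decision values.
    """
    n = len(classes)
    n_samples = dec.shape[0]
    votes = np.zeros((n_samples, n))
    score = np.zeros((n_samples, n))
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            d = dec[:, k]
            votes[:, i] += d > 0
            votes[:, j] += d <= 0
            score[:, i] += d
            score[:, j] -= d
            k += 1
    # lexicographic: votes first, summed decision values as tie-break
    eps = 1.0 / (2 * np.abs(score).max() + 1.0) if score.size else 0.0
    return classes[np.argmax(votes + eps * score, axis=1)]


def decode_features(
    X: np.ndarray,
    y: np.ndarray,
    cfg: DecodingConfig = None,
    pca_variance: float | None = None,
) -> tuple[float, np.ndarray]:
    """Stratified k-fold one-vs-one linear SVM decoding of a feature matrix.

    Returns ``(accuracy_pct, confusion)`` where the confusion matrix counts
    test predictions (rows = true class, in sorted label order) summed over
    folds.  Z-scoring and PCA are fit on each training fold only.
    """
    if cfg is None:
        cfg = DecodingConfig()
    if pca_variance is None:
        pca_variance = cfg.pca_variance
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if np.ptp(X) == 0:
        raise ValueError("features have zero variance; nothing to decode")
    skf = StratifiedKFold(
        n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed
    )
    confusion = np.zeros((classes.size, classes.size), dtype=int)
    accs = []
    for train, test in skf.split(X, y):
        scaler = StandardScaler().fit(X[train])
        Xtr = scaler.transform(X[train])
        Xte = scaler.transform(X[test])
        if np.allclose(Xtr.std(), 0):
            raise ValueError("training fold has zero variance")
        n_max = min(Xtr.shape[0], Xtr.shape[1])
        pca = PCA(n_components=min(pca_variance, 0.999999)
                  if pca_variance < 1 else n_max, svd_solver="full")
        Xtr = pca.fit_transform(Xtr)
        Xte = pca.transform(Xte)
        clf = SVC(kernel="linear", C=cfg.svm_c,
                  decision_function_shape="ovo").fit(Xtr, y[train])
        dec = np.atleast_2d(clf.decision_function(Xte))
        pred = _ovo_predict(dec, clf.classes_)
        accs.append(np.mean(pred == y[test]) * 100.0)
        for t, p in zip(y[test], pred):
            confusion[np.searchsorted(classes, t),
                      np.searchsorted(classes, p)] += 1
    return float(np.mean(accs)), confusion


def _array_data(pseudotrials: PseudotrialSet, subset, rereference: bool):
    data = pseudotrials.data[:, np.asarray(subset, dtype=int), :]
    if rereference:
        data = average_reference(data, axis=1)
    return data


def decode_timepoint(
    pseudotrials: PseudotrialSet,
    electrode_subset,
    t: int,
    cfg: DecodingConfig = None,
) -> float:
    """Cross-validated 6-way accuracy (%) at one sample index."""
    if cfg is None:
        cfg = DecodingConfig()
    data = _array_data(pseudotrials, electrode_subset, cfg.rereference)
    acc, _ = decode_features(data[:, :, t], pseudotrials.labels, cfg)
    return acc


def decode_timecourse(
    pseudotrials: PseudotrialSet,
    electrode_subset,
    cfg: DecodingConfig = None,
    array_name: str = "",
    time_window_ms: tuple | None = None,
) -> DecodingTrace:
    """Decode at every time point and characterize the early peak.

    The individual peak is the accuracy maximum within the 80-140 ms
    window; ``peak_accuracy`` averages the ``peak_average_ms`` (10 ms)
    window around it and the confusion matrix is taken at the peak sample.
    ``time_window_ms`` restricts the computed samples (the peak window is
    always included).
    """
    if cfg is None:
        cfg = DecodingConfig()
    data = _array_data(pseudotrials, electrode_subset, cfg.rereference)
    y = pseudotrials.labels
    time_ms = pseudotrials.time_ms

    mask = np.ones(time_ms.size, dtype=bool)
    if time_window_ms is not None:
        mask = (time_ms >= time_window_ms[0]) & (time_ms <= time_window_ms[1])
        half = cfg.peak_average_ms / 2.0
        mask |= (time_ms >= cfg.peak_window_ms[0] - half) & (
            time_ms <= cfg.peak_window_ms[1] + half
        )
    samples = np.flatnonzero(mask)

    acc = np.full(time_ms.size, np.nan)
    confusions = {}
    for s in samples:
        acc[s], confusions[s] = decode_features(data[:, :, s], y, cfg)

    in_peak = np.flatnonzero(
        (time_ms >= cfg.peak_window_ms[0]) & (time_ms <= cfg.peak_window_ms[1])
    )
    peak_s = in_peak[np.nanargmax(acc[in_peak])]
    half = cfg.peak_average_ms / 2.0
    around = np.flatnonzero(np.abs(time_ms - time_ms[peak_s]) <= half)
    around = around[~np.isnan(acc[around])]
    return DecodingTrace(
        time_ms=time_ms[samples],
        accuracy=acc[samples],
        array_name=array_name,
        peak_time_ms=float(time_ms[peak_s]),
        peak_accuracy=float(np.mean(acc[around])),
        confusion=confusions[peak_s],
    )


def ssvep_features(
    pseudotrials: PseudotrialSet, freq_hz: float = 15.0,
    window_ms: tuple = (0.0, 1000.0),
) -> SSVEPFeatures:
    """15 Hz amplitude per electrode from the FFT of each pseudotrial.

    The window must contain exactly ``fs * 1 s`` samples (256 at 256 Hz) so
    the tagging frequency falls on an exact 1 Hz-resolution DFT bin.
    """
    time_ms = pseudotrials.time_ms
    mask = (time_ms >= window_ms[0]) & (time_ms < window_ms[1])
    n = int(mask.sum())
    expected = int(round(pseudotrials.fs_hz * (window_ms[1] - window_ms[0]) / 1000.0))
    if n != expected:
        raise ValueError(
            f"window {window_ms} covers {n} samples; exactly {expected} required"
        )
    seg = pseudotrials.data[:, :, mask]
    spec = np.fft.rfft(seg, axis=-1)
    amps = np.abs(spec) * 2.0 / n
    bin_hz = pseudotrials.fs_hz / n
    k = int(round(freq_hz / bin_hz))
    if abs(k * bin_hz - freq_hz) > 1e-9:
        raise ValueError(f"{freq_hz} Hz is not an exact DFT bin")
    return SSVEPFeatures(amplitude=amps[:, :, k], labels=pseudotrials.labels,
                         freq_hz=freq_hz)


def pca_sweep_decode(
    features: SSVEPFeatures,
    electrode_subset,
    cfg: DecodingConfig = None,
    rereference: bool = False,
) -> dict:
    """Decode SSVEP amplitudes at each PCA variance level.

    Returns ``{"accuracy": {level: pct}, "max": best pct}``.  Amplitudes
    are nonnegative scalars per electrode, so no re-referencing is applied
    by default.
    """
    if cfg is None:
        cfg = DecodingConfig()
    X = features.amplitude[:, np.asarray(electrode_subset, dtype=int)]
    if rereference:
        X = X - X.mean(axis=1, keepdims=True)
    out = {}
    for level in cfg.pca_variance_levels:
        acc, _ = decode_features(X, features.labels, cfg, pca_variance=level)
        out[level] = acc
    return {"accuracy": out, "max": max(out.values())}


def confusion_by_condition(trace: DecodingTrace) -> np.ndarray:
    """Per-condition accuracy (%) at the peak: diagonal of the
    row-normalized confusion matrix."""
    c = trace.confusion
    if c is None or not np.any(c):
        raise ValueError("confusion matrix is empty")
    totals = c.sum(axis=1)
    return 100.0 * np.diag(c) / totals
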