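"""Representational similarity analysis (RSA).

Time-resolved EEG RDMs (electrode-count-corrected Euclidean distance
between condition ERPs), Spearman correlation against the V1 model RDM
with Fisher transformation, leave-one-subject-out noise ceilings, classical
MDS embeddings, and the Fourier analysis of the correlation trace that
exposes the 15 Hz frequency-tagged component.

The electrode-count correction divides the squared distance by the number
of electrodes (a root-mean-square distance).  This is the unique
normalization invariant under electrode duplication, and it makes absolute
dissimilarities comparable between the 128-electrode SND array and the
32-electrode ND arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .preprocess import average_reference
from .rdm import RDM, CONDITION_LABELS

__all__ = [
    "RSATrace",
    "NoiseCeiling",
    "CorrelationSpectrum",
    "eeg_rdm_at_time",
    "eeg_rdm_timecourse",
    "rsa_timecourse",
    "noise_ceiling",
    "correlation_spectrum",
    "mds_embed",
]


@dataclass
class RSATrace:
    """Model-EEG correlation per time point for one subject and array."""

    time_ms: np.ndarray
    rho: np.ndarray  # Spearman correlation, nan where undefined
    z: np.ndarray  # Fisher-transformed rho
    array_name: str = ""
    peak_time_ms: float = np.nan
    peak_value: float = np.nan  # mean z over 10 ms around the first peak

    def __post_init__(self):
        ok = ~np.isnan(self.rho)
        if np.any((self.rho[ok] < -1) | (self.rho[ok] > 1)):
            raise ValueError("rho must lie in [-1, 1]")


@dataclass
class NoiseCeiling:
    """Bounds on the best group-level correlation any model could reach."""

    lower: float
    upper: float

    def __post_init__(self):
        if self.lower > self.upper + 1e-12:
            raise ValueError("lower bound exceeds upper bound")


@dataclass
class CorrelationSpectrum:
    """Amplitude spectrum of the RSA correlation trace (1 Hz bins)."""

    freq_hz: np.ndarray
    amplitude: np.ndarray
    signal_15hz: float

    @property
    def peak_frequency_hz(self) -> float:
        """Frequency of the largest nonzero-frequency amplitude."""
        nz = self.freq_hz > 0
        return float(self.freq_hz[nz][np.argmax(self.amplitude[nz])])


def _erp_array(erps) -> np.ndarray:
    """Stack {condition: electrodes x samples} into (6, n_elec, n_samp)."""
    if isinstance(erps, dict):
        return np.stack([erps[c] for c in sorted(erps)], axis=0)
    return np.asarray(erps)


def eeg_rdm_at_time(erps, t: int, subset=None, rereference: bool = True) -> RDM:
    """RMS-distance RDM across electrodes at one sample.

    d(i, j) = sqrt( sum_e (ERP_i(e,t) - ERP_j(e,t))^2 / n_electrodes );
    dividing by the electrode count makes the value invariant under
    electrode duplication and comparable across array sizes.
    """
    arr = _erp_array(erps)
    if subset is not None:
        subset = np.asarray(subset, dtype=int)
        if subset.size < 2:
            raise ValueError("need at least 2 electrodes")
        arr = arr[:, subset, :]
    if rereference:
        arr = average_reference(arr, axis=1)
    v = arr[:, :, t]  # conditions x electrodes
    diff = v[:, None, :] - v[None, :, :]
    m = np.sqrt(np.mean(diff**2, axis=-1))
    return RDM(matrix=m, labels=CONDITION_LABELS[: m.shape[0]], source="eeg",
               normalization="per_feature_count")


def eeg_rdm_timecourse(erps, subset=None, rereference: bool = True) -> np.ndarray:
    """Condensed RDM (15 pair distances) at every sample: (n_samp, n_pairs)."""
    arr = _erp_array(erps)
    if subset is not None:
        arr = arr[:, np.asarray(subset, dtype=int), :]
    if rereference:
        arr = average_reference(arr, axis=1)
    n = arr.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    diff = arr[iu] - arr[ju]  # pairs x electrodes x samples
    return np.sqrt(np.mean(diff**2, axis=1)).T


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan  # ranks degenerate; correlation undefined
    return float(sstats.spearmanr(a, b).statistic)


def rsa_timecourse(
    model: RDM,
    erps,
    subset=None,
    time_ms: np.ndarray = None,
    peak_window_ms: tuple = (80.0, 140.0),
    peak_average_ms: float = 10.0,
    array_name: str = "",
    rereference: bool = True,
) -> RSATrace:
    """Spearman correlation between the model RDM and the EEG RDM at each
    time point, Fisher-transformed, with first-peak characterization.

    The individual first peak is the largest local maximum of z within the
    80-140 ms window (ties broken toward earlier time); ``peak_value``
    averages z over the 10 ms around it.  Undefined correlations (constant
    RDM) are recorded as NaN, never as zero.
    """
    model_v = model.condensed()
    pair_traces = eeg_rdm_timecourse(erps, subset, rereference=rereference)
    n_samp = pair_traces.shape[0]
    if time_ms is None:
        time_ms = np.arange(n_samp, dtype=float)
    rho = np.array([_spearman(model_v, pair_traces[s]) for s in range(n_samp)])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.arctanh(np.clip(rho, -1 + 1e-12, 1 - 1e-12))

    win = np.flatnonzero(
        (time_ms >= peak_window_ms[0]) & (time_ms <= peak_window_ms[1])
    )
    peak_time, peak_value = np.nan, np.nan
    if win.size:
        zw = z[win]
        # local maxima within the window (flat/edge-tolerant)
        cand = [
            k for k in range(win.size)
            if (k == 0 or not zw[k] < zw[k - 1])
            and (k == win.size - 1 or not zw[k] < zw[k + 1])
        ]
        cand = [k for k in cand if not np.isnan(zw[k])]
        if cand:
            best = max(cand, key=lambda k: (zw[k], -k))  # ties -> earlier
            s_peak = win[best]
            peak_time = float(time_ms[s_peak])
            around = np.abs(time_ms - peak_time) <= peak_average_ms / 2.0
            peak_value = float(np.nanmean(z[around]))
    return RSATrace(time_ms=np.asarray(time_ms, dtype=float), rho=rho, z=z,
                    array_name=array_name, peak_time_ms=peak_time,
                    peak_value=peak_value)


def noise_ceiling(subject_rdms: list[RDM]) -> NoiseCeiling:
    """Leave-one-subject-out noise ceiling on the group RDM correlation.

    upper: mean over subjects of Spearman(subject RDM, group-mean RDM
    including that subject); lower: the same with the subject excluded.
    """
    if len(subject_rdms) < 2:
        raise ValueError("need at least 2 subjects")
    vs = np.array([r.condensed() for r in subject_rdms])
    n = vs.shape[0]
    upper = np.mean([_spearman(vs[i], vs.mean(axis=0)) for i in range(n)])
    lower = np.mean([
        _spearman(vs[i], np.delete(vs, i, axis=0).mean(axis=0))
        for i in range(n)
    ])
    return NoiseCeiling(lower=float(lower), upper=float(upper))


def correlation_spectrum(
    values: np.ndarray,
    fs_hz: float = 256.0,
    window_s: float = 1.0,
) -> CorrelationSpectrum:
    """Amplitude spectrum of a correlation trace over the stimulus period.

    ``values`` must hold exactly ``fs_hz * window_s`` samples (256 at
    256 Hz over 0-1000 ms), giving 1 Hz bins so 15 Hz is exact.
    """
    values = np.asarray(values, dtype=float)
    n_expected = int(round(fs_hz * window_s))
    if values.size != n_expected:
        raise ValueError(
            f"trace has {values.size} samples; exactly {n_expected} required"
        )
    spec = np.fft.rfft(values)
    amp = np.abs(spec) * 2.0 / values.size
    amp[0] /= 2.0
    freqs = np.fft.rfftfreq(values.size, d=1.0 / fs_hz)
    k15 = int(round(15.0 * window_s))
    return CorrelationSpectrum(freq_hz=freqs, amplitude=amp,
                               signal_15hz=float(amp[k15]))


def mds_embed(rdm: RDM, dims: int = 2, neg_eig_tol: float = 0.2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling of an RDM.

    Double-centers the squared distances and eigendecomposes; returns the
    ``dims`` leading coordinates, centred at the origin.  Warns when the
    negative eigenvalue mass exceeds ``neg_eig_tol`` of the total (the
    distances are then far from Euclidean).
    """
    d2 = rdm.matrix**2
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    w, v = np.linalg.eigh(B)
    w, v = w[::-1], v[:, ::-1]
    neg = np.abs(w[w < 0]).sum()
    tot = np.abs(w).sum()
    if tot > 0 and neg / tot > neg_eig_tol:
        warnings.warn(
            f"negative eigenvalue mass {neg / tot:.2f} exceeds {neg_eig_tol}",
            RuntimeWarning,
        )
    coords = v[:, :dims] * np.sqrt(np.clip(w[:dims], 0.0, None))
    return coords - coords.mean(axis=0)
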