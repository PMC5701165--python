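import numpy as np
import pytest

from snyq import (
    RDM,
    CorrelationSpectrum,
    NoiseCeiling,
    correlation_spectrum,
    eeg_rdm_at_time,
    eeg_rdm_timecourse,
    mds_embed,
    noise_ceiling,
    rsa_timecourse,
)
from snyq.rsa import _spearman


def _rank_oracle(x):
    """Average ranks with tie handling, written out longhand."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size)
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _spearman_oracle(a, b):
    ra, rb = _rank_oracle(a), _rank_oracle(b)
    ra -= ra.mean()
    rb -= rb.mean()
    return float(np.sum(ra * rb) / np.sqrt(np.sum(ra**2) * np.sum(rb**2)))


# ---------------------------------------------------------------------------
# RDM container


def test_rdm_validation():
    with pytest.raises(ValueError, match="symmetric"):
        RDM(np.array([[0.0, 1.0], [2.0, 0.0]]), labels=("a", "b"))
    with pytest.raises(ValueError, match="diagonal"):
        RDM(np.array([[1.0, 0.0], [0.0, 0.0]]), labels=("a", "b"))
    with pytest.raises(ValueError, match="nonnegative"):
        RDM(np.array([[0.0, -1.0], [-1.0, 0.0]]), labels=("a", "b"))
    with pytest.raises(ValueError, match="labels"):
        RDM(np.zeros((3, 3)), labels=("a", "b"))


def test_rdm_condensed_has_15_entries():
    m = np.abs(np.arange(36.0).reshape(6, 6) - np.arange(36.0).reshape(6, 6).T)
    rdm = RDM(m)
    assert rdm.condensed().shape == (15,)
    assert rdm.entry("LVF-low", "LVF-med") == m[0, 1]


def test_rdm_tsv_round_trip(tmp_path):
    m = np.array([[0.0, 2.0, 3.0], [2.0, 0.0, 4.0], [3.0, 4.0, 0.0]])
    rdm = RDM(m, labels=("a", "b", "c"))
    p = tmp_path / "rdm.tsv"
    rdm.to_tsv(p)
    back = RDM.from_tsv(p)
    assert np.allclose(back.matrix, m)
    assert back.labels == ("a", "b", "c")


def test_rdm_mean():
    a = RDM(np.array([[0.0, 2.0], [2.0, 0.0]]), labels=("a", "b"))
    b = RDM(np.array([[0.0, 4.0], [4.0, 0.0]]), labels=("a", "b"))
    assert RDM.mean([a, b]).matrix[0, 1] == 3.0
    c = RDM(np.zeros((2, 2)), labels=("x", "y"))
    with pytest.raises(ValueError):
        RDM.mean([a, c])


# ---------------------------------------------------------------------------
# EEG RDMs


def test_eeg_rdm_hand_arithmetic():
    # two electrodes; condition ERPs [0, 0] and [3, 4] at t = 0:
    # RMS distance = sqrt((9 + 16) / 2) = sqrt(12.5)
    erps = {1: np.array([[0.0], [0.0]]), 2: np.array([[3.0], [4.0]])}
    rdm = eeg_rdm_at_time(erps, 0, rereference=False)
    assert rdm.matrix[0, 1] == pytest.approx(np.sqrt(12.5))


def test_eeg_rdm_duplication_invariance(rng):
    erps = {c: rng.normal(size=(4, 3)) for c in range(1, 7)}
    base = eeg_rdm_at_time(erps, 1, subset=[0, 1, 2, 3], rereference=False)
    dup = eeg_rdm_at_time(erps, 1, subset=[0, 1, 2, 3, 0, 1, 2, 3],
                          rereference=False)
    assert np.allclose(base.matrix, dup.matrix)


def test_eeg_rdm_timecourse_matches_single_time(rng):
    erps = {c: rng.normal(size=(5, 7)) for c in range(1, 7)}
    traces = eeg_rdm_timecourse(erps, rereference=True)
    assert traces.shape == (7, 15)
    one = eeg_rdm_at_time(erps, 3, rereference=True)
    assert np.allclose(traces[3], one.condensed())


def test_spearman_matches_rank_oracle(rng):
    for _ in range(20):
        a = rng.integers(0, 6, 15).astype(float)  # ties included
        b = rng.normal(size=15)
        if np.ptp(a) == 0:
            continue
        assert _spearman(a, b) == pytest.approx(_spearman_oracle(a, b), abs=1e-12)
    assert np.isnan(_spearman(np.ones(15), np.arange(15.0)))


# ---------------------------------------------------------------------------
# RSA time course


def _embedding_of(rdm_matrix):
    """Exact Euclidean embedding of a (Euclidean) distance matrix."""
    rdm = RDM(rdm_matrix)
    return mds_embed(rdm, dims=rdm_matrix.shape[0])


def test_rsa_timecourse_perfect_and_permuted():
    # build per-sample condition 'topographies' whose pairwise distances
    # reproduce either the model RDM (rho = 1) or a permuted version
    rng = np.random.default_rng(0)
    feats = rng.normal(size=(6, 4))
    model_m = np.zeros((6, 6))
    for i in range(6):
        for j in range(6):
            model_m[i, j] = np.linalg.norm(feats[i] - feats[j])
    model = RDM(model_m)
    pts = _embedding_of(model_m)  # 6 x 6 coordinates, exact distances
    perm = np.array([3, 0, 5, 1, 4, 2])

    n_samp = 9
    erps = np.zeros((6, 6, n_samp))
    time_ms = np.arange(n_samp) * 10.0  # 0..80 ms -> window hits 40-80
    for s in range(n_samp):
        src = pts if s in (4, 6, 8) else pts[perm]
        erps[:, :, s] = src
    trace = rsa_timecourse(model, erps, time_ms=time_ms,
                           peak_window_ms=(40.0, 80.0), peak_average_ms=0.1,
                           rereference=False)
    assert trace.rho[4] == pytest.approx(1.0)
    assert trace.rho[5] < 1.0
    # two equal local maxima at 40 and 60 ms: earlier one wins
    assert trace.peak_time_ms == 40.0
    assert trace.peak_value == pytest.approx(np.arctanh(1 - 1e-12))


def test_rsa_trace_validation():
    from snyq import RSATrace

    with pytest.raises(ValueError):
        RSATrace(time_ms=np.array([0.0]), rho=np.array([1.5]),
                 z=np.array([0.0]))


# ---------------------------------------------------------------------------
# noise ceiling


def test_noise_ceiling_loo_enumeration(rng):
    vs = [rng.normal(size=15) for _ in range(3)]
    rdms = []
    from scipy.spatial.distance import squareform

    for v in vs:
        rdms.append(RDM(squareform(np.abs(v))))
    vals = np.array([r.condensed() for r in rdms])
    upper = np.mean([_spearman_oracle(vals[i], vals.mean(0)) for i in range(3)])
    lower = np.mean([
        _spearman_oracle(vals[i], np.delete(vals, i, 0).mean(0))
        for i in range(3)
    ])
    nc = noise_ceiling(rdms)
    assert nc.upper == pytest.approx(upper, abs=1e-12)
    assert nc.lower == pytest.approx(lower, abs=1e-12)
    with pytest.raises(ValueError):
        noise_ceiling(rdms[:1])


def test_noise_ceiling_validation():
    with pytest.raises(ValueError):
        NoiseCeiling(lower=0.9, upper=0.5)


# ---------------------------------------------------------------------------
# correlation spectrum


def test_correlation_spectrum_oracle():
    fs = 256.0
    t = np.arange(256) / fs
    x = 0.3 + 0.8 * np.sin(2 * np.pi * 15.0 * t) + 0.1 * np.sin(2 * np.pi * 4.0 * t)
    spec = correlation_spectrum(x, fs_hz=fs)
    assert spec.signal_15hz == pytest.approx(0.8, abs=1e-9)
    assert spec.amplitude[0] == pytest.approx(0.3, abs=1e-9)  # DC not doubled
    assert spec.peak_frequency_hz == 15.0  # DC excluded from the peak
    with pytest.raises(ValueError, match="samples"):
        correlation_spectrum(x[:200], fs_hz=fs)


def test_peak_frequency_excludes_dc():
    spec = CorrelationSpectrum(
        freq_hz=np.array([0.0, 1.0, 2.0]),
        amplitude=np.array([10.0, 0.2, 0.5]),
        signal_15hz=0.0,
    )
    assert spec.peak_frequency_hz == 2.0


# ---------------------------------------------------------------------------
# MDS


def test_mds_recovers_triangle():
    # 3-4-5 right triangle
    m = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
    rdm = RDM(m, labels=("a", "b", "c"))
    pts = mds_embed(rdm, dims=2)
    rec = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    assert np.allclose(rec, m, atol=1e-9)
    assert np.allclose(pts.mean(axis=0), 0.0, atol=1e-9)


def test_mds_warns_on_non_euclidean():
    # severely non-Euclidean distances (triangle inequality violated)
    m = np.array([[0.0, 10.0, 1.0], [10.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
    rdm = RDM(m, labels=("a", "b", "c"))
    with pytest.warns(RuntimeWarning):
        mds_embed(rdm, dims=2, neg_eig_tol=0.01)
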