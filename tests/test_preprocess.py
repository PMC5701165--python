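import numpy as np
import pytest

import snyq
from snyq import (
    EpochedData,
    RawSession,
    RejectionRules,
    average_reference,
    epoch_and_baseline,
    filter_and_decimate,
    grand_erp,
    make_pseudotrials,
    reject_trials_and_electrodes,
)


def _session(data, labels, fs=512.0, event_sample=None, blocks=None, layout=None):
    data = np.asarray(data, dtype=np.float32)
    if layout is None:
        layout = snyq.make_layout(n_cols=data.shape[1], n_rows=1)
    if event_sample is None:
        event_sample = data.shape[2] // 2
    if blocks is None:
        blocks = np.ones(data.shape[0], dtype=int)
    return RawSession(
        data=data, labels=np.asarray(labels), blocks=np.asarray(blocks),
        fs_hz=fs, event_sample=event_sample, layout=layout,
    )


def _epochs(data, labels, fs=256.0, time_ms=None, blocks=None):
    data = np.asarray(data, dtype=float)
    if time_ms is None:
        time_ms = (np.arange(data.shape[2]) - 1) * 1000.0 / fs
    if blocks is None:
        blocks = np.ones(data.shape[0], dtype=int)
    return EpochedData(
        data=data, labels=np.asarray(labels), blocks=np.asarray(blocks),
        fs_hz=fs, time_ms=np.asarray(time_ms, dtype=float),
    )


# ---------------------------------------------------------------------------
# epoching and baseline


def test_baseline_subtraction_hand_oracle():
    # fs = 10 Hz, window (-200, 300) ms -> offsets -2..3; baseline is the
    # mean of the two pre-onset samples: (1 + 3) / 2 = 2
    trace = np.arange(1.0, 21.0, 2.0)  # 1, 3, 5, ..., 19
    sess = _session(trace.reshape(1, 1, -1), [1], fs=10.0, event_sample=5)
    ep = epoch_and_baseline(sess, window_ms=(-200.0, 300.0))
    assert np.allclose(ep.time_ms, [-200, -100, 0, 100, 200, 300])
    # samples at offsets -2..3 are 7, 9, 11, 13, 15, 17; baseline (7+9)/2 = 8
    assert np.allclose(ep.data[0, 0], [-1, 1, 3, 5, 7, 9])


def test_epoch_window_exceeds_recording():
    sess = _session(np.zeros((1, 1, 10)), [1], fs=10.0, event_sample=5)
    with pytest.raises(ValueError, match="exceeds"):
        epoch_and_baseline(sess, window_ms=(-200.0, 600.0))


def test_average_reference_zero_mean():
    x = np.arange(24.0).reshape(2, 3, 4)
    y = average_reference(x)
    assert np.allclose(y.mean(axis=1), 0.0)
    assert np.allclose(y[:, 0] - y[:, 1], x[:, 0] - x[:, 1])


# ---------------------------------------------------------------------------
# filtering and decimation


def test_filter_preserves_passband_and_rejects_stopband():
    # the 0.1 Hz high-pass edge transient decays over ~10 s, so probe with a
    # long signal and measure in the middle third
    fs, dur = 512.0, 30.0
    t = np.arange(int(fs * dur)) / fs
    layout = snyq.make_layout(n_cols=3, n_rows=1)
    sig = np.stack([np.sin(2 * np.pi * 15 * t),
                    np.sin(2 * np.pi * 60 * t),
                    np.sin(2 * np.pi * 150 * t)])
    sess = _session(sig[None], [1], fs=fs, event_sample=0, layout=layout)
    out = filter_and_decimate(sess, target_fs=512)  # isolate the band-pass
    mid = slice(int(10 * fs), int(20 * fs))
    seg = out.data[0, :, mid].astype(float)
    n = seg.shape[1]
    # exact-bin amplitudes (150 cycles of 15 Hz over the 10 s window);
    # the residual low-frequency edge transient does not leak this high
    amps = [2.0 * np.abs(np.fft.rfft(seg[k])[f * 10]) / n
            for k, f in ((0, 15), (1, 60), (2, 150))]
    assert abs(amps[0] - 1.0) < 0.01           # 15 Hz within 1%
    assert amps[1] < 0.01                      # 60 Hz notch: > 40 dB down
    assert amps[2] < 0.1                       # 150 Hz: > 20 dB down


def test_decimation_halves_rate():
    sess = _session(np.zeros((2, 1, 1024)), [1, 2], fs=512.0, event_sample=256)
    out = filter_and_decimate(sess)
    assert out.fs_hz == 256.0
    assert out.data.shape == (2, 1, 512)
    assert out.event_sample == 128
    assert out.data.dtype == np.float32


def test_filter_input_validation():
    sess = _session(np.zeros((1, 1, 512)), [1], fs=512.0)
    with pytest.raises(ValueError, match="divisor"):
        filter_and_decimate(sess, target_fs=300)
    slow = _session(np.zeros((1, 1, 512)), [1], fs=128.0)
    with pytest.raises(ValueError, match="twice"):
        filter_and_decimate(slow)


def test_global_reference_option():
    rng = np.random.default_rng(0)
    sess = _session(rng.normal(size=(2, 4, 512)), [1, 2], fs=512.0)
    out = filter_and_decimate(sess, target_fs=512, reference="global")
    assert np.allclose(out.data.mean(axis=1), 0.0, atol=1e-5)


# ---------------------------------------------------------------------------
# rejection


def _lenient(**kw):
    defaults = dict(trial_voltage_uv=150.0, max_bad_channels_decoding=10,
                    max_bad_channels_erp=25, electrode_std_limit=1e9,
                    electrode_bad_trial_fraction=0.999)
    defaults.update(kw)
    return RejectionRules(**defaults)


def test_decoding_rejection_strict_threshold():
    # trial 0: 11 channels over -> rejected; trial 1: 10 channels -> kept
    data = np.zeros((3, 12, 4))
    data[0, :11, 2] = 200.0
    data[1, :10, 2] = 200.0
    ep = _epochs(data, [1, 1, 1])
    out = reject_trials_and_electrodes(ep, _lenient(), mode="decoding")
    assert out.n_trials == 2
    assert np.array_equal(out.kept_trial_ids, [1, 2])
    assert any(k == "trial" and i == 0 for k, i, _ in out.rejection_report)


def test_erp_rejection_only_checks_early_window():
    # excursions after 300 ms do not reject in erp mode
    fs = 256.0
    n = 200
    time_ms = (np.arange(n) - 51) * 1000.0 / fs  # -199..578 ms
    data = np.zeros((2, 30, n))
    data[0, :26, time_ms > 400] = 200.0   # late: ignored
    data[1, :26, (time_ms > 50) & (time_ms < 250)] = 200.0  # early: rejected
    ep = _epochs(data, [1, 1], fs=fs, time_ms=time_ms)
    out = reject_trials_and_electrodes(ep, _lenient(), mode="erp")
    assert np.array_equal(out.kept_trial_ids, [0])


def test_electrode_rejection_rules():
    # electrode 0 over threshold on 2 of 3 trials (> 0.5) -> dropped;
    # electrode 1 with a huge-variance grand ERP -> dropped by the std rule
    data = np.zeros((3, 5, 8))
    data[0, 0, 3] = 200.0
    data[1, 0, 3] = 200.0
    data[:, 1, :] = np.linspace(-30, 30, 8)  # grand ERP std ~ 20
    ep = _epochs(data, [1, 2, 1])
    rules = _lenient(max_bad_channels_decoding=10, electrode_std_limit=5.0,
                     electrode_bad_trial_fraction=0.5)
    out = reject_trials_and_electrodes(ep, rules, mode="decoding")
    assert out.n_trials == 3  # no trial has > 10 bad channels
    assert np.array_equal(out.kept_electrode_ids, [2, 3, 4])
    kinds = {(k, i) for k, i, _ in out.rejection_report}
    assert ("electrode", 0) in kinds and ("electrode", 1) in kinds


def test_eye_movement_flags():
    data = np.zeros((4, 3, 8))
    ep = _epochs(data, [1, 2, 1, 2])
    out = reject_trials_and_electrodes(
        ep, _lenient(), mode="decoding",
        eye_movement_flags=np.array([True, False, False, True]),
    )
    assert np.array_equal(out.kept_trial_ids, [1, 2])


def test_emptied_condition_raises():
    data = np.zeros((2, 12, 4))
    data[0, :, :] = 500.0  # the only trial of condition 2 is rejected
    ep = _epochs(data, [2, 1])
    with pytest.raises(ValueError, match=r"condition\(s\) \[2\]"):
        reject_trials_and_electrodes(ep, _lenient(), mode="decoding")


def test_rejection_idempotent():
    rng = np.random.default_rng(1)
    data = rng.normal(0, 60, size=(20, 12, 16))
    ep = _epochs(data, rng.integers(1, 3, 20))
    once = reject_trials_and_electrodes(ep, mode="decoding")
    twice = reject_trials_and_electrodes(once, mode="decoding")
    assert np.array_equal(once.kept_trial_ids, twice.kept_trial_ids)
    assert np.array_equal(once.kept_electrode_ids, twice.kept_electrode_ids)
    assert np.array_equal(once.data, twice.data)


# ---------------------------------------------------------------------------
# pseudotrials and ERPs


def _balanced_epochs(n_per_cond=80, n_elec=2, n_samp=3, n_cond=2, seed=0):
    rng = np.random.default_rng(seed)
    n = n_per_cond * n_cond
    labels = np.repeat(np.arange(1, n_cond + 1), n_per_cond)
    blocks = np.tile(1 + np.arange(n_per_cond) % 10, n_cond)
    data = rng.normal(size=(n, n_elec, n_samp))
    return _epochs(data, labels, blocks=blocks)


def test_pseudotrial_bookkeeping_and_averaging():
    ep = _balanced_epochs()
    ps = make_pseudotrials(ep, 80, seed=1)
    assert ps.n_per_condition == 40
    assert ps.n_pseudotrials == 80  # 2 conditions x 40
    assert np.array_equal(np.sort(np.unique(ps.labels)), [1, 2])
    # every pseudotrial is the mean of its recorded source pair
    for k, (i, j) in enumerate(ps.provenance):
        assert np.allclose(ps.data[k], (ep.data[i] + ep.data[j]) / 2.0)
    # pairs span the two session halves
    for i, j in ps.provenance:
        assert ep.blocks[i] <= 5 and ep.blocks[j] > 5
    # seeded determinism
    ps2 = make_pseudotrials(ep, 80, seed=1)
    assert np.array_equal(ps.data, ps2.data)
    ps3 = make_pseudotrials(ep, 80, seed=2)
    assert not np.array_equal(ps.data, ps3.data)


def test_pseudotrials_insufficient_trials():
    ep = _balanced_epochs(n_per_cond=30)
    with pytest.raises(ValueError, match="condition 1"):
        make_pseudotrials(ep, 80)
    with pytest.raises(ValueError, match="even"):
        make_pseudotrials(ep, 21)


def test_grand_erp_means():
    data = np.array([
        [[1.0, 2.0]], [[3.0, 6.0]],  # condition 1 -> mean [2, 4]
        [[10.0, 0.0]],               # condition 2
    ])
    ep = _epochs(data, [1, 1, 2])
    erps = grand_erp(ep)
    assert np.allclose(erps[1], [[2.0, 4.0]])
    assert np.allclose(erps[2], [[10.0, 0.0]])
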