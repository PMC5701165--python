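"""Preprocessing: filtering, decimation, epoching, artifact rejection,
pseudotrial averaging and ERP construction.

The chain follows the study's recipe: zero-phase 0.1-100 Hz band-pass (plus
an optional line-noise notch), average reference, decimation from 512 to
256 Hz, epoching to (-200, +1300) ms around stimulus onset with a -200..0 ms
baseline correction, amplitude-based trial and electrode rejection, and
2-trial pseudotrial averaging (80 accepted trials per condition -> 40
pseudotrials, 240 in total).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .simulate import RawSession

logger = logging.getLogger(__name__)

__all__ = [
    "EpochedData",
    "PseudotrialSet",
    "RejectionRules",
    "average_reference",
    "filter_and_decimate",
    "epoch_and_baseline",
    "reject_trials_and_electrodes",
    "make_pseudotrials",
    "grand_erp",
]


@dataclass
class EpochedData:
    """Baseline-corrected epochs: trials x electrodes x samples."""

    data: np.ndarray
    labels: np.ndarray
    blocks: np.ndarray
    fs_hz: float
    time_ms: np.ndarray
    baseline_window_ms: tuple = (-200.0, 0.0)
    kept_trial_ids: np.ndarray = None
    kept_electrode_ids: np.ndarray = None
    rejection_report: list = field(default_factory=list)

    def __post_init__(self):
        if self.kept_trial_ids is None:
            self.kept_trial_ids = np.arange(self.data.shape[0])
        if self.kept_electrode_ids is None:
            self.kept_electrode_ids = np.arange(self.data.shape[1])
        if np.any(np.diff(self.time_ms) <= 0):
            raise ValueError("time axis must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def condition_counts(self) -> dict:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def sample_at(self, t_ms: float) -> int:
        """Index of the sample nearest to ``t_ms``."""
        return int(np.argmin(np.abs(self.time_ms - t_ms)))


@dataclass
class PseudotrialSet:
    """Averages of trial pairs used for classification."""

    data: np.ndarray
    labels: np.ndarray
    fs_hz: float
    time_ms: np.ndarray
    n_per_condition: int
    provenance: list = field(default_factory=list)

    @property
    def n_pseudotrials(self) -> int:
        return self.data.shape[0]


@dataclass
class RejectionRules:
    """Amplitude-based rejection thresholds (all comparisons strict)."""

    trial_voltage_uv: float = 150.0
    max_bad_channels_decoding: int = 10
    max_bad_channels_erp: int = 25
    erp_check_window_ms: tuple = (0.0, 300.0)
    electrode_std_limit: float = 5.0
    electrode_bad_trial_fraction: float = 0.5

    def __post_init__(self):
        for v in (self.trial_voltage_uv, self.max_bad_channels_decoding,
                  self.max_bad_channels_erp, self.electrode_std_limit,
                  self.electrode_bad_trial_fraction):
            if v <= 0:
                raise ValueError("all thresholds must be positive")


def average_reference(data: np.ndarray, axis: int = 1) -> np.ndarray:
    """Subtract the mean across electrodes at each sample.

    Applied within whichever electrode array is being analysed (SND or one
    ND subset), so each array is self-referenced; referencing is linear and
    per-sample, hence commutes with the temporal filters.
    """
    return data - data.mean(axis=axis, keepdims=True)


def filter_and_decimate(
    session: RawSession,
    band_hz: tuple = (0.1, 100.0),
    notch_hz: float | None = 60.0,
    target_fs: int = 256,
    reference: str | None = None,
) -> RawSession:
    """Zero-phase band-pass, optional notch, decimate; optional global
    average reference (``reference='global'``).

    The notch stands in for the effective output of a full line-noise
    pipeline on clean data; no channels are interpolated.  By default
    referencing is deferred to analysis time, where each electrode array is
    average-referenced within itself.
    """
    fs = session.fs_hz
    if fs < 2 * band_hz[1]:
        raise ValueError("sampling rate below twice the band upper edge")
    q, rem = divmod(int(round(fs)), int(target_fs))
    if rem:
        raise ValueError(
            f"target_fs={target_fs} is not an integer divisor of fs={fs}"
        )
    sos = sps.butter(4, band_hz, btype="bandpass", fs=fs, output="sos")
    if notch_hz:
        sos = np.vstack([sos, sps.tf2sos(*sps.iirnotch(notch_hz, Q=30.0, fs=fs))])

    data = session.data
    n_trials = data.shape[0]
    chunks = []
    step = max(1, int(2e8 // max(data[0].nbytes, 1)))
    for start in range(0, n_trials, step):
        block = data[start:start + step].astype(np.float64)
        block = sps.sosfiltfilt(sos, block, axis=-1)
        if reference == "global":
            block = average_reference(block, axis=1)
        if q > 1:
            block = sps.decimate(block, q, axis=-1, zero_phase=True)
        chunks.append(block.astype(np.float32))
    out = np.concatenate(chunks) if len(chunks) > 1 else chunks[0]
    return RawSession(
        data=out,
        labels=session.labels,
        blocks=session.blocks,
        fs_hz=float(target_fs),
        event_sample=session.event_sample // q,
        layout=session.layout,
    )


def epoch_and_baseline(
    session: RawSession, window_ms: tuple = (-200.0, 1300.0)
) -> EpochedData:
    """Cut epochs around stimulus onset and subtract the baseline mean.

    The baseline is the per-trial, per-electrode mean over (-200, 0) ms.
    Trials whose window would run past the recording edge are dropped with a
    warning.
    """
    fs = session.fs_hz
    start = int(np.ceil(window_ms[0] * fs / 1000.0))
    stop = int(np.floor(window_ms[1] * fs / 1000.0))
    offsets = np.arange(start, stop + 1)
    time_ms = offsets * 1000.0 / fs

    n_samp = session.data.shape[2]
    ev = session.event_sample
    if ev + start < 0 or ev + stop >= n_samp:
        raise ValueError("epoch window exceeds the trial recording")

    data = session.data[:, :, ev + start: ev + stop + 1].astype(np.float64)
    base_mask = time_ms < 0.0
    baseline = data[:, :, base_mask].mean(axis=-1, keepdims=True)
    data -= baseline
    return EpochedData(
        data=data,
        labels=session.labels.copy(),
        blocks=session.blocks.copy(),
        fs_hz=fs,
        time_ms=time_ms,
    )


def reject_trials_and_electrodes(
    epochs: EpochedData, rules: RejectionRules = None, mode: str = "decoding",
    eye_movement_flags: np.ndarray | None = None,
) -> EpochedData:
    """Apply the study's amplitude rejection rules.

    decoding mode: drop a trial when more than ``max_bad_channels_decoding``
    channels exceed |trial_voltage_uv| anywhere in the trial.  erp mode:
    drop a trial when more than ``max_bad_channels_erp`` electrodes exceed
    the threshold within the 0-300 ms check window.  Electrodes are then
    dropped if over threshold on more than half of the kept trials, or if
    the standard deviation of their grand-average ERP trace exceeds
    ``electrode_std_limit``.  ``eye_movement_flags`` (per original trial)
    marks externally detected horizontal eye movements; flagged trials are
    dropped first.
    """
    if rules is None:
        rules = RejectionRules()
    if mode not in ("decoding", "erp"):
        raise ValueError("mode must be 'decoding' or 'erp'")
    report = list(epochs.rejection_report)
    data, labels, blocks = epochs.data, epochs.labels, epochs.blocks
    trial_ids = epochs.kept_trial_ids
    thr = rules.trial_voltage_uv

    keep = np.ones(data.shape[0], dtype=bool)
    if eye_movement_flags is not None:
        flags = np.asarray(eye_movement_flags, dtype=bool)[trial_ids]
        keep &= ~flags
        for tid in trial_ids[flags]:
            report.append(("trial", int(tid), "horizontal eye movement"))

    if mode == "decoding":
        over = np.any(np.abs(data) > thr, axis=-1)  # trials x electrodes
        n_bad = over.sum(axis=1)
        bad = n_bad > rules.max_bad_channels_decoding
        rule = f">{rules.max_bad_channels_decoding} channels over {thr:g} uV"
    else:
        w0, w1 = rules.erp_check_window_ms
        win = (epochs.time_ms >= w0) & (epochs.time_ms <= w1)
        over = np.any(np.abs(data[:, :, win]) > thr, axis=-1)
        n_bad = over.sum(axis=1)
        bad = n_bad > rules.max_bad_channels_erp
        rule = (f">{rules.max_bad_channels_erp} electrodes over {thr:g} uV "
                f"in {w0:g}-{w1:g} ms")
    for tid in trial_ids[keep & bad]:
        report.append(("trial", int(tid), rule))
    keep &= ~bad

    data, labels, blocks = data[keep], labels[keep], blocks[keep]
    trial_ids = trial_ids[keep]

    # electrode rejection on the kept trials
    elec_keep = np.ones(data.shape[1], dtype=bool)
    if data.shape[0]:
        over = np.any(np.abs(data) > thr, axis=-1)  # kept trials x electrodes
        frac = over.mean(axis=0)
        bad_frac = frac > rules.electrode_bad_trial_fraction
        grand = data.mean(axis=0)  # electrodes x samples
        bad_std = grand.std(axis=-1, ddof=0) > rules.electrode_std_limit
        for e in np.flatnonzero(bad_frac):
            report.append(("electrode", int(epochs.kept_electrode_ids[e]),
                           f"over {thr:g} uV on >{rules.electrode_bad_trial_fraction:.0%} of trials"))
        for e in np.flatnonzero(bad_std & ~bad_frac):
            report.append(("electrode", int(epochs.kept_electrode_ids[e]),
                           f"grand ERP std > {rules.electrode_std_limit:g}"))
        elec_keep = ~(bad_frac | bad_std)

    present = set(np.unique(labels).tolist())
    missing = sorted(set(np.unique(epochs.labels).tolist()) - present)
    if missing:
        raise ValueError(f"all trials rejected for condition(s) {missing}")
    if report:
        logger.info("rejection removed %d items", len(report) - len(epochs.rejection_report))

    return EpochedData(
        data=data[:, elec_keep, :],
        labels=labels,
        blocks=blocks,
        fs_hz=epochs.fs_hz,
        time_ms=epochs.time_ms,
        baseline_window_ms=epochs.baseline_window_ms,
        kept_trial_ids=trial_ids,
        kept_electrode_ids=epochs.kept_electrode_ids[elec_keep],
        rejection_report=report,
    )


def make_pseudotrials(
    epochs: EpochedData, n_keep_per_condition: int = 80, seed: int = 0
) -> PseudotrialSet:
    """Average seeded random trial pairs into pseudotrials.

    Per condition, ``n_keep_per_condition`` accepted trials are drawn at
    random (half from blocks 1-5, half from blocks 6-10 when possible) and
    averaged in first-half/second-half pairs, halving the trial count while
    reducing non-stimulus noise.
    """
    if n_keep_per_condition % 2:
        raise ValueError("n_keep_per_condition must be even")
    rng = np.random.default_rng(seed)
    half_n = n_keep_per_condition // 2
    out, out_labels, prov = [], [], []
    for cond in sorted(np.unique(epochs.labels).tolist()):
        idx = np.flatnonzero(epochs.labels == cond)
        if idx.size < n_keep_per_condition:
            raise ValueError(
                f"condition {cond} has only {idx.size} accepted trials; "
                f"{n_keep_per_condition} required"
            )
        first = idx[epochs.blocks[idx] <= 5]
        second = idx[epochs.blocks[idx] > 5]
        if first.size >= half_n and second.size >= half_n:
            a = rng.choice(first, half_n, replace=False)
            b = rng.choice(second, half_n, replace=False)
        else:
            logger.warning(
                "condition %d: block halves unbalanced; pairing at random", cond
            )
            chosen = rng.choice(idx, n_keep_per_condition, replace=False)
            a, b = chosen[:half_n], chosen[half_n:]
        rng.shuffle(a)
        rng.shuffle(b)
        out.append((epochs.data[a] + epochs.data[b]) / 2.0)
        out_labels.append(np.full(half_n, cond))
        prov.extend(
            (int(epochs.kept_trial_ids[i]), int(epochs.kept_trial_ids[j]))
            for i, j in zip(a, b)
        )
    return PseudotrialSet(
        data=np.concatenate(out),
        labels=np.concatenate(out_labels),
        fs_hz=epochs.fs_hz,
        time_ms=epochs.time_ms,
        n_per_condition=half_n,
        provenance=prov,
    )


def grand_erp(epochs: EpochedData) -> dict:
    """Mean ERP trace per condition: {condition: electrodes x samples}."""
    erps = {}
    for cond in sorted(np.unique(epochs.labels).tolist()):
        sel = epochs.labels == cond
        if not sel.any():
            raise ValueError(f"no trials for condition {cond}")
        erps[int(cond)] = epochs.data[sel].mean(axis=0)
    if not erps:
        raise ValueError("no trials at all")
    return erps
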