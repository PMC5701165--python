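"""Study orchestration and I/O.

Holds the run configuration, the per-session array+JSON container, a
BDF/EDF import path for real recordings (plus a minimal EDF writer used to
round-trip synthetic sessions in tests), and ``run_study`` — the end-to-end
driver: simulate (or import) -> preprocess -> time-domain decoding ->
frequency-domain (SSVEP) decoding -> RSA -> group statistics -> report
tables.  Fully deterministic given the configuration seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .decoding import (
    DecodingConfig,
    confusion_by_condition,
    decode_timecourse,
    pca_sweep_decode,
    ssvep_features,
)
from .hmax import GaborBankSpec, model_rdm, s1_filter
from .layout import ARRAY_NAMES, ElectrodeLayout, make_layout
from .preprocess import (
    RejectionRules,
    epoch_and_baseline,
    filter_and_decimate,
    grand_erp,
    make_pseudotrials,
    reject_trials_and_electrodes,
)
from .rdm import RDM
from .rsa import correlation_spectrum, eeg_rdm_at_time, noise_ceiling, rsa_timecourse
from .simulate import RawSession, SimulationConfig, simulate_session
from .stimuli import stimulus_set

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "StudyReport",
    "build_model_rdm",
    "run_study",
    "save_session",
    "load_session",
    "write_edf",
    "import_bdf",
]


@dataclass
class RunConfig:
    """Everything needed to reproduce one end-to-end run."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    rules: RejectionRules = field(default_factory=RejectionRules)
    decoding: DecodingConfig = field(default_factory=DecodingConfig)
    arrays: tuple = ARRAY_NAMES
    analyses: tuple = ("time", "freq", "rsa")
    n_keep_per_condition: int = 80
    layout_geometry: str = "flat_patch"
    decode_time_window_ms: tuple | None = None  # None = all samples
    stimulus_pixels_per_degree: float = 128.0 / 56.0
    reference_per_array: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    """Tidy result tables of the three analyses plus group statistics."""

    peak_decoding: pd.DataFrame  # subject, array, peak_time_ms, peak_accuracy
    freq_decoding: pd.DataFrame  # subject, array, variance_level, accuracy
    rsa_peak: pd.DataFrame  # subject, array, peak_time_ms, peak_z, signal_15hz
    condition_accuracy: pd.DataFrame  # subject, array, condition, accuracy
    group_rsa_trace: pd.DataFrame  # array, time_ms, mean_z
    effects: list = field(default_factory=list)
    noise_ceilings: dict = field(default_factory=dict)
    spectra: dict = field(default_factory=dict)
    config_hash: str = ""

    def tables(self) -> dict:
        return {
            "peak_decoding": self.peak_decoding,
            "freq_decoding": self.freq_decoding,
            "rsa_peak": self.rsa_peak,
            "condition_accuracy": self.condition_accuracy,
            "group_rsa_trace": self.group_rsa_trace,
        }

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables().items():
            df2 = df.copy()
            df2["config_hash"] = self.config_hash
            df2.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        meta = {
            "config_hash": self.config_hash,
            "effects": [dataclasses.asdict(e) for e in self.effects],
            "noise_ceilings": {
                k: dataclasses.asdict(v) for k, v in self.noise_ceilings.items()
            },
        }
        (out / "report.json").write_text(json.dumps(meta, indent=2, default=float))


def build_model_rdm(pixels_per_degree: float = 128.0 / 56.0,
                    bank: GaborBankSpec = None) -> RDM:
    """HMAX-S1 RDM of the six rendered checkerboard stimuli."""
    responses = [
        s1_filter(_render(spec, pixels_per_degree), bank)
        for spec in stimulus_set()
    ]
    return model_rdm(responses)


def _render(spec, ppd):
    from .stimuli import render_checkerboard

    return render_checkerboard(spec, ppd, phase=0)


def _subject_tables(cfg: RunConfig, layout: ElectrodeLayout, model: RDM,
                    subject_id: int) -> dict:
    """Run all configured analyses for one subject; returns row dicts."""
    session = simulate_session(cfg.sim, layout, subject_id)
    clean = filter_and_decimate(session)
    del session
    epochs = epoch_and_baseline(clean, cfg.sim.epoch_window_ms)
    del clean

    out = {"peak": [], "freq": [], "rsa": [], "cond": [], "traces": {},
           "rdm_at_peak": {}}
    dec_cfg = dataclasses.replace(cfg.decoding, seed=cfg.decoding.seed + subject_id)

    if "time" in cfg.analyses or "freq" in cfg.analyses:
        kept = reject_trials_and_electrodes(epochs, cfg.rules, mode="decoding")
        pseudo = make_pseudotrials(
            kept, cfg.n_keep_per_condition, seed=cfg.sim.seed * 1000 + subject_id
        )
        subsets = {
            name: _kept_subset(layout, kept.kept_electrode_ids, name)
            for name in cfg.arrays
        }
        if "time" in cfg.analyses:
            for name in cfg.arrays:
                trace = decode_timecourse(
                    pseudo, subsets[name], dec_cfg, array_name=name,
                    time_window_ms=cfg.decode_time_window_ms,
                )
                out["peak"].append(
                    dict(subject=subject_id, array=name,
                         peak_time_ms=trace.peak_time_ms,
                         peak_accuracy=trace.peak_accuracy)
                )
                for cond, acc in enumerate(confusion_by_condition(trace), 1):
                    out["cond"].append(
                        dict(subject=subject_id, array=name, condition=cond,
                             accuracy=acc)
                    )
        if "freq" in cfg.analyses:
            feats = ssvep_features(pseudo)
            for name in cfg.arrays:
                sweep = pca_sweep_decode(feats, subsets[name], dec_cfg)
                for level, acc in sweep["accuracy"].items():
                    out["freq"].append(
                        dict(subject=subject_id, array=name,
                             variance_level=level, accuracy=acc)
                    )

    if "rsa" in cfg.analyses:
        kept_erp = reject_trials_and_electrodes(epochs, cfg.rules, mode="erp")
        erps = grand_erp(kept_erp)
        for name in cfg.arrays:
            subset = _kept_subset(layout, kept_erp.kept_electrode_ids, name)
            trace = rsa_timecourse(
                model, erps, subset, time_ms=kept_erp.time_ms,
                array_name=name, rereference=cfg.reference_per_array,
            )
            stim_mask = (trace.time_ms >= 0) & (trace.time_ms < 1000.0)
            spec = correlation_spectrum(
                np.nan_to_num(trace.z[stim_mask]), fs_hz=kept_erp.fs_hz
            )
            out["rsa"].append(
                dict(subject=subject_id, array=name,
                     peak_time_ms=trace.peak_time_ms, peak_z=trace.peak_value,
                     signal_15hz=spec.signal_15hz)
            )
            out["traces"][name] = trace
            if not np.isnan(trace.peak_time_ms):
                t_peak = int(np.argmin(np.abs(kept_erp.time_ms - trace.peak_time_ms)))
                out["rdm_at_peak"][name] = eeg_rdm_at_time(
                    erps, t_peak, subset, rereference=cfg.reference_per_array
                )
    return out


def _kept_subset(layout: ElectrodeLayout, kept_electrode_ids: np.ndarray,
                 array_name: str) -> np.ndarray:
    """Positions (within the kept-electrode axis) of one array's channels."""
    wanted = set(layout.array_indices(array_name).tolist())
    return np.flatnonzero(np.isin(kept_electrode_ids, list(wanted)))


def run_study(cfg: RunConfig = None, out_dir=None) -> StudyReport:
    """Run the full study on synthetic subjects and assemble the report.

    Stages per subject: simulate -> filter/decimate -> epoch/baseline ->
    reject -> pseudotrials -> decoding (time and/or frequency domain) and
    RSA against the HMAX-S1 model RDM; then group statistics (array-effect
    repeated-measures ANOVA, SND-vs-ND paired t-tests) over subjects.
    """
    from .stats import paired_t_gav, rm_anova

    if cfg is None:
        cfg = RunConfig()
    layout = make_layout(cfg.layout_geometry, seed=cfg.sim.seed)
    model = (build_model_rdm(cfg.stimulus_pixels_per_degree)
             if "rsa" in cfg.analyses else None)

    rows = {"peak": [], "freq": [], "rsa": [], "cond": []}
    traces_by_array = {name: [] for name in cfg.arrays}
    rdms_by_array = {name: [] for name in cfg.arrays}
    for subject_id in range(cfg.sim.n_subjects):
        logger.info("subject %d", subject_id)
        res = _subject_tables(cfg, layout, model, subject_id)
        for key in rows:
            rows[key].extend(res[key])
        for name, tr in res["traces"].items():
            traces_by_array[name].append(tr)
        for name, r in res["rdm_at_peak"].items():
            rdms_by_array[name].append(r)

    peak = pd.DataFrame(rows["peak"])
    freq = pd.DataFrame(rows["freq"])
    rsa_df = pd.DataFrame(rows["rsa"])
    cond = pd.DataFrame(rows["cond"])

    group_trace_rows = []
    spectra = {}
    for name, traces in traces_by_array.items():
        if not traces:
            continue
        zs = np.nanmean([t.z for t in traces], axis=0)
        tms = traces[0].time_ms
        group_trace_rows.append(
            pd.DataFrame({"array": name, "time_ms": tms, "mean_z": zs})
        )
        stim = (tms >= 0) & (tms < 1000.0)
        if stim.sum():
            try:
                spectra[name] = correlation_spectrum(
                    np.nan_to_num(zs[stim]), fs_hz=1000.0 / np.diff(tms).mean() / 1.0
                )
            except ValueError:
                pass
    group_trace = (pd.concat(group_trace_rows, ignore_index=True)
                   if group_trace_rows else pd.DataFrame())

    ceilings = {
        name: noise_ceiling(rdms) for name, rdms in rdms_by_array.items()
        if len(rdms) >= 2
    }

    effects = []
    n_subj = cfg.sim.n_subjects
    if n_subj >= 3 and len(cfg.arrays) >= 2:
        for label, df, value in (
            ("peak decoding", peak, "peak_accuracy"),
            ("rsa peak z", rsa_df, "peak_z"),
        ):
            if len(df):
                tab = df.rename(columns={value: "value"})
                effects.extend(
                    _relabel(rm_anova(tab, dv="value"), label)
                )
                effects.extend(_snd_vs_nd(tab, cfg.arrays, label, paired_t_gav))
        if len(freq):
            tab = freq.rename(columns={"accuracy": "value",
                                       "variance_level": "level"})
            effects.extend(
                _relabel(
                    rm_anova(tab, dv="value", within=["array", "level"]),
                    "freq decoding",
                )
            )
            best = (tab.groupby(["subject", "array"], as_index=False)["value"]
                    .max())
            effects.extend(_snd_vs_nd(best, cfg.arrays, "freq decoding max",
                                      paired_t_gav))

    report = StudyReport(
        peak_decoding=peak, freq_decoding=freq, rsa_peak=rsa_df,
        condition_accuracy=cond, group_rsa_trace=group_trace,
        effects=effects, noise_ceilings=ceilings, spectra=spectra,
        config_hash=cfg.config_hash(),
    )
    if out_dir is not None:
        report.save(out_dir)
        (Path(out_dir) / "config.json").write_text(
            json.dumps(cfg.to_dict(), indent=2, default=str)
        )
    return report


def _relabel(reports, prefix):
    for r in reports:
        r.name = f"{prefix}: {r.name}"
    return reports


def _snd_vs_nd(df: pd.DataFrame, arrays, label, paired_t_gav):
    out = []
    if "SND" not in set(df["array"]):
        return out
    snd = df[df["array"] == "SND"].sort_values("subject")["value"].to_numpy()
    for name in arrays:
        if name == "SND":
            continue
        nd = df[df["array"] == name].sort_values("subject")["value"].to_numpy()
        out.append(paired_t_gav(snd, nd, name=f"{label}: SND vs {name}"))
    return out


# ---------------------------------------------------------------------------
# session container: one binary array file + JSON sidecar per subject

def save_session(session: RawSession, out_dir, subject_id: int,
                 config_hash: str = "") -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = f"subject{subject_id:03d}"
    np.save(out / f"{stem}_data.npy", session.data)
    session.layout.to_tsv(out / f"{stem}_layout.tsv")
    sidecar = {
        "subject_id": subject_id,
        "labels": session.labels.tolist(),
        "blocks": session.blocks.tolist(),
        "fs_hz": session.fs_hz,
        "event_sample": session.event_sample,
        "config_hash": config_hash,
    }
    (out / f"{stem}.json").write_text(json.dumps(sidecar))
    return out / f"{stem}.json"


def load_session(sidecar_path) -> RawSession:
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    stem = sidecar_path.stem
    data = np.load(sidecar_path.with_name(f"{stem}_data.npy"))
    layout = ElectrodeLayout.from_tsv(sidecar_path.with_name(f"{stem}_layout.tsv"))
    return RawSession(
        data=data,
        labels=np.asarray(meta["labels"]),
        blocks=np.asarray(meta["blocks"]),
        fs_hz=meta["fs_hz"],
        event_sample=meta["event_sample"],
        layout=layout,
    )


# ---------------------------------------------------------------------------
# EDF import/export

def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(session: RawSession, path) -> None:
    """Write a session as a plain 16-bit EDF file (synthetic-test writer).

    Trials are concatenated into one continuous signal per electrode, plus
    a 'Status' stimulus channel holding the condition code at each trial's
    onset sample.  One data record per trial.  Intended for round-trip
    testing of the import path, not for archival use.
    """
    n_trials, n_elec, n_samp = session.data.shape
    fs = session.fs_hz
    record_s = n_samp / fs

    stim = np.zeros((n_trials, n_samp), dtype=np.float64)
    stim[:, session.event_sample] = session.labels

    sigs = [session.data[:, e, :].astype(np.float64) for e in range(n_elec)]
    sigs.append(stim)
    labels = [f"EEG{e:03d}" for e in range(n_elec)] + ["Status"]

    phys_min, phys_max, digitized = [], [], []
    for k, sig in enumerate(sigs):
        if k == n_elec:  # Status: identity scaling keeps codes exact
            phys_min.append(-32768.0)
            phys_max.append(32767.0)
            digitized.append(np.round(sig).astype("<i2"))
            continue
        lo = float(min(sig.min(), -1.0))
        hi = float(max(sig.max(), 1.0))
        phys_min.append(lo)
        phys_max.append(hi)
        scale = (hi - lo) / 65535.0
        d = np.round((sig - lo) / scale - 32768.0).astype("<i2")
        digitized.append(d)

    ns = len(sigs)
    header = b"".join([
        _ascii("0", 8), _ascii("synthetic", 80), _ascii("snyq session", 80),
        _ascii("01.01.00", 8), _ascii("00.00.00", 8),
        _ascii(256 * (1 + ns), 8), _ascii("", 44),
        _ascii(n_trials, 8), _ascii(f"{record_s:g}", 8), _ascii(ns, 4),
    ])
    fields = [
        b"".join(_ascii(lbl, 16) for lbl in labels),
        b"".join(_ascii("", 80) for _ in sigs),
        b"".join(_ascii("uV", 8) for _ in sigs),
        b"".join(_ascii(f"{v:.8g}"[:8], 8) for v in phys_min),
        b"".join(_ascii(f"{v:.8g}"[:8], 8) for v in phys_max),
        b"".join(_ascii(-32768, 8) for _ in sigs),
        b"".join(_ascii(32767, 8) for _ in sigs),
        b"".join(_ascii("", 80) for _ in sigs),
        b"".join(_ascii(n_samp, 8) for _ in sigs),
        b"".join(_ascii("", 32) for _ in sigs),
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for f in fields:
            fh.write(f)
        for rec in range(n_trials):
            for d in digitized:
                fh.write(d[rec].tobytes())


def import_bdf(
    path,
    layout: ElectrodeLayout,
    event_map: dict | None = None,
    stim_channel: str = "Status",
    pre_s: float = 0.5,
    post_s: float = 1.5,
) -> RawSession:
    """Import a BDF/EDF recording as a trial-split RawSession.

    Events are read from the stimulus channel; ``event_map`` remaps raw
    event codes to the condition codes 1..6.  Trials are cut from
    ``pre_s`` before to ``post_s`` after each event.  Block tags are
    assigned by splitting the trial sequence into ten equal runs.
    """
    import mne

    path = Path(path)
    reader = (mne.io.read_raw_bdf if path.suffix.lower() == ".bdf"
              else mne.io.read_raw_edf)
    raw = reader(path, stim_channel=stim_channel, preload=True, verbose="error")
    fs = raw.info["sfreq"]
    picks = [ch for ch in raw.ch_names if ch != stim_channel]
    if stim_channel not in raw.ch_names:
        raise ValueError(f"stimulus channel {stim_channel!r} not found")
    stim = raw.get_data(picks=[stim_channel])[0]
    onsets = np.flatnonzero((stim > 0.5) & np.r_[True, stim[:-1] <= 0.5])
    if onsets.size == 0:
        raise ValueError("no events found in the stimulus channel")
    codes = np.round(stim[onsets]).astype(int)
    if event_map is not None:
        unknown = sorted(set(codes.tolist()) - set(event_map))
        if unknown:
            raise ValueError(f"unknown event codes {unknown}")
        codes = np.array([event_map[c] for c in codes])
    if not np.all((codes >= 1) & (codes <= 6)):
        raise ValueError("event codes must map to conditions 1..6")

    eeg = raw.get_data(picks=picks) * 1e6  # mne stores volts
    pre = int(round(pre_s * fs))
    post = int(round(post_s * fs))
    trials = []
    kept_codes = []
    for onset, code in zip(onsets, codes):
        if onset - pre < 0 or onset + post > eeg.shape[1]:
            logger.warning("event at sample %d too close to edge; dropped", onset)
            continue
        trials.append(eeg[:, onset - pre: onset + post])
        kept_codes.append(code)
    data = np.stack(trials).astype(np.float32)
    blocks = 1 + (np.arange(len(trials)) * 10) // max(len(trials), 1)
    return RawSession(
        data=data,
        labels=np.asarray(kept_codes),
        blocks=np.clip(blocks, 1, 10),
        fs_hz=fs,
        event_sample=pre,
        layout=layout,
    )
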