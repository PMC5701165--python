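"""Synthetic multi-subject EEG sessions with volume-conduction structure.

The generator emulates the study's recordings at the level the analyses
need: six stimulus conditions (3 radial spatial frequencies x 2 hemifields),
a 15 Hz pattern-reversal steady-state response lasting 1000 ms, an onset
transient peaking ~105 ms after stimulus onset, condition topographies that
are contralateral scalp patterns whose dominant spatial wavelength scales
with stimulus spatial frequency, Gaussian spatial blur standing in for
volume conduction through skull and scalp, and spatially correlated sensor
noise.  Everything is deterministic given the config seed and subject id.

The physics being emulated: cortical sources produce scalp patterns that
are low-pass filtered in space by volume conduction, so high-spatial-
frequency patterns arrive attenuated.  The default scalp wavelengths
(80/55/38 mm for low/medium/high stimulus SF) straddle the Nyquist limits
of the 28 mm ND arrays (56 mm) and the 14 mm SND array (28 mm), which is
what makes electrode density matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .layout import ElectrodeLayout

__all__ = [
    "SimulationConfig",
    "RawSession",
    "simulate_session",
    "condition_topographies",
    "topography_grid",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic session generator.

    ``n_trials_per_condition`` and ``fs_hz`` follow the study design
    (100 repeats per condition over 10 blocks; 512 Hz digitization); the
    forward-model parameters (blur width, scalp wavelengths, noise
    correlation length, snr) are simulator choices, not measured values.
    """

    n_subjects: int = 16
    n_trials_per_condition: int = 100
    fs_hz: int = 512
    epoch_window_ms: tuple = (-200.0, 1300.0)
    blur_fwhm_mm: float = 25.0
    source_sf_map: dict = field(
        default_factory=lambda: {0.036: 80.0, 0.071: 55.0, 0.143: 38.0}
    )
    snr: float = 0.065
    noise_spatial_corr_mm: float = 40.0
    white_noise_frac: float = 0.25
    noise_std_uv: float = 1.0
    flicker_hz: float = 15.0
    stim_duration_s: float = 1.0
    onset_latency_s: float = 0.105
    onset_width_s: float = 0.025
    onset_gain: float = 1.0
    reversal_width_s: float = 0.010
    envelope_sigma_mm: float = 35.0
    envelope_offset_mm: float = 40.0
    subject_jitter_mm: float = 3.0
    subject_phase_jitter: float = 0.15
    trial_onset_s: float = 0.5
    trial_duration_s: float = 2.0
    n_blocks: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0 or self.n_trials_per_condition <= 0:
            raise ValueError("counts must be positive")
        if self.blur_fwhm_mm < 0:
            raise ValueError("blur_fwhm_mm must be >= 0")
        if self.n_trials_per_condition % self.n_blocks:
            raise ValueError("n_trials_per_condition must divide into blocks")


@dataclass
class RawSession:
    """One subject's simulated (or imported) recording, already split into
    trials: trials x electrodes x samples, in microvolts."""

    data: np.ndarray
    labels: np.ndarray
    blocks: np.ndarray
    fs_hz: float
    event_sample: int
    layout: ElectrodeLayout

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.blocks = np.asarray(self.blocks, dtype=int)
        if self.data.shape[0] != self.labels.shape[0]:
            raise ValueError("labels/data trial count mismatch")
        if self.data.shape[1] != self.layout.n_electrodes:
            raise ValueError(
                f"data has {self.data.shape[1]} electrodes but layout has "
                f"{self.layout.n_electrodes}"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


def _grid(layout: ElectrodeLayout, step_mm: float = 2.0, margin_mm: float = 40.0):
    pos = layout.positions
    x0, x1 = pos[:, 0].min() - margin_mm, pos[:, 0].max() + margin_mm
    y0, y1 = pos[:, 1].min() - margin_mm, pos[:, 1].max() + margin_mm
    gx = np.arange(x0, x1 + step_mm, step_mm)
    gy = np.arange(y0, y1 + step_mm, step_mm)
    return gx, gy


def topography_grid(
    cfg: SimulationConfig,
    layout: ElectrodeLayout,
    condition: int,
    subject_id: int = 0,
    blur_fwhm_mm: float | None = None,
    step_mm: float = 2.0,
):
    """Condition scalp topography on a fine flat-patch grid.

    Returns ``(gx, gy, pattern)`` where ``pattern`` has shape
    ``(len(gy), len(gx))``.  The source pattern is an isotropic narrowband
    random field -- a sum of plane waves at the condition's scalp
    wavelength (``cfg.source_sf_map``) with random orientations and
    phases -- under a Gaussian envelope centred over the hemisphere
    contralateral to the stimulated hemifield.  The wave orientations and
    phases are drawn per subject and hemifield (individual cortical
    folding) and shared by the three spatial-frequency conditions of that
    hemifield, with phases anchored at the envelope centre, so
    topographies of nearby wavelengths stay spatially coherent (their
    correlation decays as ``exp(-|dk|^2 sigma^2 / 2)`` with wavenumber
    separation) while the two hemifields' patterns are independent.
    After the volume-conduction blur the pattern is
    normalized to unit RMS over the electrode patch: the stimuli are
    cortically magnification-scaled, so all conditions evoke responses of
    comparable scalp amplitude and differ in spatial structure, not gain.
    """
    from .stimuli import RADIAL_SFS

    if not 1 <= condition <= 6:
        raise ValueError("condition must be in 1..6")
    if blur_fwhm_mm is None:
        blur_fwhm_mm = cfg.blur_fwhm_mm
    hemi_i, sf_i = divmod(condition - 1, 3)  # 0=left field, 1=right field
    lam = cfg.source_sf_map[RADIAL_SFS[sf_i]]

    rng = np.random.default_rng([int(cfg.seed), int(subject_id), 101])
    dx, dy = rng.normal(0.0, cfg.subject_jitter_mm, 2)
    phase_jit = rng.normal(0.0, cfg.subject_phase_jitter, 6)

    # per-subject, per-hemifield carrier wave set (cortical folding)
    wave_rng = np.random.default_rng(
        [int(cfg.seed), int(subject_id), int(hemi_i), 303]
    )
    n_waves = 16
    thetas = wave_rng.uniform(0.0, np.pi, n_waves)
    phis = wave_rng.uniform(0.0, 2.0 * np.pi, n_waves)

    # contralateral response: left-field stimulus -> right hemisphere
    cx = (cfg.envelope_offset_mm if hemi_i == 0 else -cfg.envelope_offset_mm) + dx
    cy = float(np.mean(layout.positions[:, 1])) + dy

    gx, gy = _grid(layout, step_mm=step_mm)
    X, Y = np.meshgrid(gx, gy)
    env = np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * cfg.envelope_sigma_mm**2))
    k = 2.0 * np.pi / lam
    carrier = np.zeros_like(X)
    # phases anchored at the envelope centre: conditions of the same
    # hemifield with nearby wavelengths then correlate positively
    for theta, phi in zip(thetas, phis):
        carrier += np.cos(
            k * ((X - cx) * np.cos(theta) + (Y - cy) * np.sin(theta))
            + phi + phase_jit[condition - 1]
        )
    pattern = env * carrier

    if blur_fwhm_mm > 0:
        pattern = gaussian_filter(
            pattern, sigma=blur_fwhm_mm * _FWHM_TO_SIGMA / step_mm, mode="nearest"
        )

    # unit RMS over the electrode patch after blurring
    sampled = _sample_grid(gx, gy, pattern, layout.positions)
    rms = np.sqrt(np.mean(sampled**2))
    if rms > 0:
        pattern = pattern / rms
    return gx, gy, pattern


def _sample_grid(gx, gy, pattern, positions):
    from scipy.interpolate import RegularGridInterpolator

    interp = RegularGridInterpolator(
        (gy, gx), pattern, bounds_error=False, fill_value=0.0
    )
    return interp(np.column_stack([positions[:, 1], positions[:, 0]]))


def condition_topographies(
    cfg: SimulationConfig, layout: ElectrodeLayout, subject_id: int = 0
) -> np.ndarray:
    """Per-electrode signal weights for the six conditions: (6, n_elec)."""
    topos = []
    for cond in range(1, 7):
        gx, gy, pattern = topography_grid(cfg, layout, cond, subject_id)
        topos.append(_sample_grid(gx, gy, pattern, layout.positions))
    return np.asarray(topos)


def _dog_wavelet(t: np.ndarray, peak_s: float, sigma_s: float) -> np.ndarray:
    """Biphasic (derivative-of-Gaussian) deflection, unit positive peak.

    Zero-mean in time, so the slow high-pass filter leaves it intact; the
    positive lobe peaks at ``peak_s``.
    """
    u = (t - peak_s + sigma_s) / sigma_s
    return u * np.exp(-(u**2) / 2.0) * np.exp(0.5)


def _gauss_pulse(t: np.ndarray, peak_s: float, sigma_s: float) -> np.ndarray:
    """Monophasic Gaussian deflection with unit positive peak at ``peak_s``.

    The reversal train uses one-signed pulses deliberately: a non-negative
    profile is invariant under magnitude-sensitive measures (|s| = s), so
    quantities locked to the response magnitude -- such as the model-EEG
    correlation trace -- keep their spectral peak at the reversal
    fundamental instead of doubling at the lobe alternation rate, as a
    zero-mean biphasic train would force.  The train's slow pedestal
    (mean level ~0.19 of the pulse peak for the default width) sits well
    above the 0.1 Hz high-pass corner over the 1 s stimulus, so the
    band-pass passes the shape essentially unchanged.
    """
    u = (t - peak_s) / sigma_s
    return np.exp(-(u**2) / 2.0)


def _temporal_profile(cfg: SimulationConfig, t: np.ndarray) -> np.ndarray:
    """Stimulus-locked response time course (t in seconds, 0 = onset).

    An onset transient (biphasic deflection peaking at ``onset_latency_s``,
    the P1-like component) plus a reversal-locked steady-state train: one
    monophasic P100-like deflection per pattern reversal at ``flicker_hz``
    per second for the stimulus duration.  Zero before onset.
    """
    s = cfg.onset_gain * _dog_wavelet(t, cfg.onset_latency_s, cfg.onset_width_s)
    reversal_times = np.arange(0.0, cfg.stim_duration_s, 1.0 / cfg.flicker_hz)
    lat = 2.0 * cfg.reversal_width_s  # small response latency per reversal
    for tk in reversal_times:
        s = s + _gauss_pulse(t, tk + lat, cfg.reversal_width_s)
    return np.where(t >= 0, s, 0.0)


def _noise_cholesky(cfg: SimulationConfig, layout: ElectrodeLayout) -> np.ndarray:
    pos = layout.positions
    d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
    ell2 = cfg.noise_spatial_corr_mm**2
    cov = (1.0 - cfg.white_noise_frac) * np.exp(-d2 / (2 * ell2))
    cov += cfg.white_noise_frac * np.eye(pos.shape[0])
    cov *= cfg.noise_std_uv**2
    # small relative ridge for numerical safety
    ridge = 1e-10 * max(float(np.mean(np.diag(cov))), 1e-300)
    return np.linalg.cholesky(cov + ridge * np.eye(pos.shape[0]))


def _trial_order(cfg: SimulationConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """Balanced condition labels and block tags, shuffled within block."""
    per_block = cfg.n_trials_per_condition // cfg.n_blocks
    labels, blocks = [], []
    for b in range(cfg.n_blocks):
        block_labels = np.repeat(np.arange(1, 7), per_block)
        rng.shuffle(block_labels)
        labels.append(block_labels)
        blocks.append(np.full(block_labels.size, b + 1))
    return np.concatenate(labels), np.concatenate(blocks)


def simulate_session(
    cfg: SimulationConfig, layout: ElectrodeLayout, subject_id: int
) -> RawSession:
    """Simulate one subject's session: 10 blocks of balanced trials.

    Each trial is ``trial_duration_s`` long with stimulus onset at
    ``trial_onset_s``; the condition topography (contralateral blurred
    grating) is modulated by the onset transient and the 15 Hz reversal
    train, with amplitude ``snr * noise_std_uv``, on top of spatially
    correlated Gaussian noise.  Byte-identical for identical
    ``(cfg.seed, subject_id)``.
    """
    cfg.validate()
    n_elec = layout.n_electrodes
    n_samples = int(round(cfg.trial_duration_s * cfg.fs_hz))
    event_sample = int(round(cfg.trial_onset_s * cfg.fs_hz))
    t = (np.arange(n_samples) - event_sample) / cfg.fs_hz

    rng = np.random.default_rng([int(cfg.seed), int(subject_id), 202])
    labels, blocks = _trial_order(cfg, rng)
    n_trials = labels.size

    topos = condition_topographies(cfg, layout, subject_id)
    profile = _temporal_profile(cfg, t)
    amp = cfg.snr * cfg.noise_std_uv
    L = _noise_cholesky(cfg, layout).astype(np.float32)

    data = np.empty((n_trials, n_elec, n_samples), dtype=np.float32)
    signal = np.einsum("ce,s->ces", topos, profile).astype(np.float32) * amp
    chunk = max(1, int(2e8 // (n_elec * n_samples * 4)))
    for start in range(0, n_trials, chunk):
        stop = min(start + chunk, n_trials)
        z = rng.standard_normal(
            (stop - start, n_elec, n_samples), dtype=np.float32
        )
        noise = np.einsum("ef,tfs->tes", L, z)
        data[start:stop] = noise + signal[labels[start:stop] - 1]

    return RawSession(
        data=data,
        labels=labels,
        blocks=blocks,
        fs_hz=float(cfg.fs_hz),
        event_sample=event_sample,
        layout=layout,
    )
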