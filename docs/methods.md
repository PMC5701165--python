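# Methods

This document records how the synthetic study is generated and analysed,
and why the generator parameters have the values they do. The defaults of
`SimulationConfig`, `RejectionRules`, `DecodingConfig` and `RunConfig` *are*
the study conditions; analyses and tests run against them unchanged.

## Electrode layouts

`make_layout` places a 16 x 8 grid over occipital cortex with 14 mm pitch
and 0.5 mm Gaussian position jitter (128 electrodes, the super-Nyquist
density array, "SND"). The four Nyquist-density subsets ND1..ND4 are the
parity sublattices `(row % 2) * 2 + (col % 2)`, each a 8 x 4 grid with
~28 mm pitch. With scalp wavelengths of 80 / 55 / 38 mm for the low /
medium / high spatial-frequency responses (see below), the ND arrays
(spatial Nyquist wavelength 2 x 28 = 56 mm) undersample the high-SF
pattern while the SND array (Nyquist 28 mm) resolves all three. A
`spherical_cap` geometry projects the same grid onto a 95 mm sphere via an
azimuthal-equidistant map; this compresses tangential chords slightly, so
its median spacing is ~12 mm rather than 14 mm.

## Signal generator

Each trial is 2 s at 512 Hz with stimulus onset at 0.5 s. A trial is
`noise + snr_gain * topography (x) temporal_profile`:

* **Topographies.** Each condition's scalp pattern is an isotropic
  narrowband random field -- a sum of 16 plane waves at the condition's
  scalp wavelength (80 / 55 / 38 mm by spatial frequency) with random
  orientations and phases -- under a Gaussian envelope (sigma 35 mm)
  centred 40 mm contralateral to the stimulated hemifield, then low-pass
  blurred with a 25 mm FWHM Gaussian kernel (volume conduction) and
  normalized to unit RMS over the electrode patch. The wave set is drawn
  per subject and hemifield (individual cortical folding) and shared by
  the three spatial-frequency conditions of a hemifield, with phases
  anchored at the envelope centre; topographies of nearby wavelengths
  then correlate as `exp(-|dk|^2 sigma^2 / 2)`, giving a
  representational geometry in which within-hemifield dissimilarity
  grows with spatial-frequency separation and cross-hemifield patterns
  are independent -- the structure the V1 model RDM also has. Post-blur
  normalization encodes the stimuli being cortically
  magnification-scaled: all conditions evoke comparable scalp
  amplitudes and differ in spatial structure, not gain. (An earlier
  design -- a single x-oriented cosine carrier, normalized before blur --
  produced two artifacts: an amplitude confound that made all high-SF
  RDM distances small, and carrier phase-locking between the hemifield
  centres and with the ND column parities; both inverted or scrambled
  the model correlation orderings, so it was replaced.) Per-subject
  variability additionally includes 3 mm envelope-centre jitter and a
  small per-condition phase jitter.
* **Temporal profile.** One biphasic derivative-of-Gaussian onset
  transient (`u * exp(-u^2 / 2)`, peak-normalized, zero-mean) peaking at
  105 ms (sigma 25 ms, gain 1.0), plus a train of *monophasic* Gaussian
  P100-like reversal responses at 15 per second (sigma 10 ms, latency
  2 sigma after each reversal) for the 1 s stimulus. The reversal pulses
  are one-signed deliberately: the model-EEG correlation trace tracks
  the instantaneous *magnitude* of the evoked pattern, and any zero-mean
  biphasic reversal response crosses zero twice per period, which makes
  that trace's spectrum peak at a harmonic (30 or 45 Hz) instead of the
  15 Hz fundamental -- verified empirically for derivative-of-Gaussian
  and asymmetric-rebound shapes before settling on monophasic pulses. A
  non-negative profile satisfies |s| = s, so the magnitude trace
  inherits the signed train's fundamental-dominant spectrum. The
  train's slow pedestal (~0.19 of pulse peak, i.e. ~0.01 uV at study
  snr) passes the 0.1 Hz high-pass essentially unchanged and is
  negligible against 1 uV noise in the baseline. A reversal-locked
  transient train was chosen over a "fundamental + 2nd harmonic"
  sinusoid sketch because only the former gives transient time-domain
  VEPs alongside the 15 Hz steady-state component.
* **Noise.** Spatially correlated Gaussian noise (squared-exponential
  covariance, 40 mm length scale, 25% white fraction, unit variance,
  sampled through a Cholesky factor with a relative ridge of
  `1e-10 * mean(diag)`), independent across samples. Temporally this is
  white; the 0.1-100 Hz band-pass shapes it afterwards.
* **snr.** The single calibration constant, fixed once at 0.065 so that
  group-mean peak 6-way decoding on the full array lands in the tens of
  percent above chance and clearly off ceiling, the scale reported for
  the original recordings (~74% peak on the dense array). It was not
  adjusted after observing any acceptance-test outcome.

A consequence worth knowing: noise below ~1 Hz survives the high-pass,
and baseline correction anchors it at zero at trial start, so
single-subject correlation traces can drift late in the epoch with a
random per-subject sign. The drift averages out at the group level; the
15 Hz component does not, because it is stimulus-locked.

Seeding: topographies use `default_rng([seed, subject, 101])`, trial
order and noise use `default_rng([seed, subject, 202])`, so any subject
can be regenerated alone, independent of `n_subjects`.

## Preprocessing

Zero-phase (forward-backward SOS) 4th-order Butterworth band-pass
0.1-100 Hz plus a Q = 30 notch at 60 Hz; decimation 512 to 256 Hz;
epoching to -200..+1300 ms around onset with mean-baseline subtraction
over t < 0. Rejection (strict `>` comparisons, trials before
electrodes): trial absolute amplitude > 150 uV; electrode rejected if
> 25% of its trials exceed threshold; trial rejected if > 10% of its
electrodes exceed threshold; electrode std > 5 x median electrode std;
optional eye-movement flags; "erp" mode additionally drops a trial when
more than half its electrodes are flagged. Pseudotrials: the first 80
accepted trials per condition (block-balanced: blocks 1-5 pair with
blocks 6-10) are averaged in pairs, giving 40 pseudotrials per condition,
240 in total.

## Decoding

Per fold (stratified 10-fold): standardize, PCA (full SVD) retaining 99%
variance, linear SVM (C = 1) one-vs-one over the six conditions.
Prediction is by OvO vote count with ties broken by the summed signed
decision values (equivalent to scikit-learn's
`_ovr_decision_function`; libsvm's own `predict` breaks vote ties
arbitrarily, so it is not used). Time-resolved decoding classifies the
instantaneous scalp pattern at every retained sample; the reported peak
accuracy averages +-5 ms around the maximum inside 80-140 ms, and that
peak window is always computed even when a restricted `time_window_ms`
is requested. Frequency-domain decoding takes each electrode's 15 Hz
Fourier amplitude over the exact 256-sample post-onset window and sweeps
PCA variance retention over 10..90% and 99%. Empirical chance is 16.66%.

## RSA

EEG RDMs use RMS-normalized Euclidean distances between average-referenced
condition ERPs across the electrode subset (invariant under electrode
duplication, so array size does not trivially inflate distances). The
model RDM is Euclidean distance between HMAX S1 feature vectors (Gabor
filters, 4 orientations x 16 sizes from the standard S1 parameter table,
local-L2-normalized, zero-padded borders) of the six rendered stimuli at
128 px / 56 deg. Model-EEG agreement is Spearman correlation over the 15
unique pairs, Fisher z-transformed; the trace peak is the largest local
maximum in 80-140 ms (earlier wins ties), averaged +-5 ms. The amplitude
spectrum of the 0-1000 ms trace is `2 |rfft| / N` (DC not doubled and
excluded from the peak search). Noise ceilings are the usual
mean-RDM/leave-one-out Spearman bounds. MDS is classical (Torgerson).

## Statistics

Repeated-measures ANOVA via pingouin (generalized eta squared), handling
both of pingouin's output layouts (`p-unc`/`p_unc`, `ddof1`/per-row `DF`).
Paired comparisons use `scipy.stats.ttest_rel` with Hedges g_av; error
bars use Cousineau-Morey within-subject SEMs. For 16 subjects x 5 arrays
the array effect is F(4, 60).

## Acceptance targets

* **t1** - mean 6-way decoding over all pre-stimulus (t < 0) time points
  on the SND array, 16 subjects. No condition-locked signal exists before
  onset, so this estimates empirical chance; it must fall inside the 99%
  binomial interval around 1/6 with n = 16 x 240 decisions
  (~15.12-18.22%).
* **t3** - the frequency of the largest nonzero bin in the amplitude
  spectrum of the group-mean model-EEG correlation trace over 0-1000 ms
  (256 samples at 256 Hz, 1 Hz resolution): 15 Hz, the pattern-reversal
  rate.

`scripts/acceptance.py` recomputes both from scratch (simulation through
analysis) and writes them as JSON.

## Problem sizes and runtime

One subject at study defaults: 600 trials x 128 electrodes x 1024
samples (float32, ~300 MB transient peak during simulation, processed in
chunks). Full 16-subject acceptance run: roughly 15-20 minutes on one
CPU, dominated by the per-timepoint SVM cross-validation. Unit tests run
in ~2 minutes; the acceptance tests share a single module-scoped
16-subject fixture.
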