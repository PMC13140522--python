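# Methods

`nirsdca` assesses dynamic cerebral autoregulation (dCA) from simultaneous
arterial blood pressure (ABP) and NIRS oxyhaemoglobin (OxyHb) recordings by
transfer function analysis (TFA) of spontaneous low-frequency oscillations,
and provides the statistical stage for hemisphere/covariate/time-segment
comparisons of the resulting phase shifts. Because clinical recordings of
this kind are rarely shareable, the package ships a synthetic-recording
generator with exact ground truth; every stage is validated against it or
against an analytic oracle.

## Signal model and pipeline

**Inputs.** An ABP waveform (mmHg) and per-channel NIRS signals, either
vendor-converted OxyHb (µM·mm) or two-wavelength optical density. Channels
carry montage metadata: hemisphere (ischaemic / contralateral), 35 mm
source–detector separation for the three cortical ("long") channels per
hemisphere, 10 mm for the scalp-sensitive ("short") channel.

**Beer–Lambert conversion** (`mbll`). ΔOD(λ) = Σ_c ε(λ,c)·ΔC(c)·DPF(λ),
inverted per sample for (ΔHbO2, ΔHbR). Outputs stay pathlength-scaled
(µM·mm): we never divide by the separation, so no partial-pathlength factor
is assumed. Default extinction coefficients (760/850 nm, Cope compilation,
converted to OD per µM·mm) and DPF 6.0 are configuration, not asserted
truth — the upstream constants any given device used are generally unknown.

**Preprocessing** (`preprocess`). Transient artifacts are flagged by two
robust criteria and replaced by linear interpolation between the nearest
clean samples:

* *amplitude*: robust z-score (median/MAD, threshold 5) of the residual
  after removing a 10 s rolling-median baseline, scored on a 0.6 Hz
  low-passed version of the residual so systolic peaks never trip it;
* *derivative*: first-difference outliers mark discontinuities; the flag
  goes to the sample farther from the local baseline, which localizes an
  isolated spike to exactly its own sample. The threshold is floored at
  twice the 99.9th percentile of observed slopes because waveforms spend
  only a small duty cycle on their steepest (systolic) upstroke and a plain
  MAD scale would flag it.

Flagged runs longer than `max_gap_s` (default 5 s) are reported as
unsalvageable. Note a baseline-offset artifact longer than the rolling
median window cannot be fully masked by construction; such epochs fail the
segment artifact-density rule instead.

Beats are detected on the ABP waveform as maxima of the first derivative
(systolic upstroke feet) after zero-phase 15 Hz smoothing, with a 0.3 s
refractory period and parabolic sub-sample refinement. All signals — ABP
and every OxyHb channel — are reduced to per-beat means on this single
ABP-derived beat grid, placed at beat-interval midpoints, and linearly
interpolated onto a uniform 10 Hz grid. Using one beat clock keeps the
ABP–OxyHb relative timing exact, which is what the phase estimate depends
on; the ~2% amplitude attenuation that beat-averaging applies to a 0.1 Hz
oscillation is common to input and output and cancels in the gain ratio.

**Steady-state segments** (`segments`). Analysis windows are 5 min. A
window qualifies when every monitored vital (HR, mean ABP, SpO2, ETCO2)
varies by at most 10% — interpreted as (max − min)/window mean, the
reference being otherwise unspecified — the artifact density stays below 5%
per signal, and the window avoids the exclusion zones: 5 min after
anaesthesia induction and 2 min after any substantial anaesthetic/opioid/
vasopressor change (operationalized as any drug-change event marker).
Candidate windows advance on a 1 s stride inside each label's eligibility
interval: PRE (induction → first recanalization attempt) and POST (final
reperfusion status → anaesthesia termination) take the earliest admissible
window, the 2H segment (anaesthesia termination → recanalization + 2 h)
takes the latest ("as late as possible"). Selection provably equals an
exhaustive scan because it *is* an exhaustive scan with early exit; the
test oracle re-implements it independently.

**Transfer function analysis** (`tfa`). Welch auto-/cross-spectra with
100 s Hann windows, 50% overlap, per-window mean removal (guideline-style
defaults; all configurable). H(f) = S_xy/S_xx; gain |H| (µM·mm/mmHg),
coherence |S_xy|²/(S_xx·S_yy), and phase reported with the clinical sign
convention — positive when OxyHb follows ABP, negative when it precedes —
i.e. the negative of arg H under the e^{−iωt} DFT convention, verified by
the pure-delay oracle (1 s delay → +36° at 0.1 Hz). Band averages over VLF
(0.02–0.07), LF (0.07–0.2) and HF (0.2–0.5 Hz):

* gain and coherence: input-power-weighted bin means. Weighting matters for
  narrowband records (a noiseless Mayer-wave line leaves most LF bins with
  no input power, where |H| is 0/0); it reduces to the plain mean for
  frequency-flat spectra.
* phase: circular mean weighted by |S_xy|, so noise-dominated bins do not
  pull the band phase.

Normalized gain (%/%) is gain × mean ABP / output scale; the output scale
(a reference OxyHb amplitude) must be supplied by the caller because OxyHb
is a change signal whose mean is near zero, making percent-of-mean
ill-defined. No coherence gating is applied by default; estimates and
coherence are reported side by side.

**180° consistency correction.** Occasionally a single channel's band phase
sits 180° from its hemisphere's other long channels (plausibly a
low-amplitude artefact). If exactly one channel lies 180° ± 30° (circular)
from the circular mean of the remaining channels, and those remaining
channels agree among themselves within 30°, the deviant is shifted by 180°
and flagged; any other pattern — including two deviants — is left
untouched. Phases live on the principal interval (−180°, 180°].

## Statistics (`stats`)

Side-to-side comparisons use paired tests on per-subject ischaemic −
contralateral differences: paired t when a Shapiro–Wilk screen (α = 0.05)
does not reject normality of the differences, Wilcoxon signed-rank
otherwise. Degenerate zero-variance nonzero differences report p = 0.
Multiple comparisons are Benjamini–Hochberg adjusted (`fdr_adjust`),
validated bin-for-bin against the step-up definition.

Phase models are linear mixed-effects fits (REML, statsmodels MixedLM) with
a subject random intercept and fixed effects from hemisphere, covariates,
time segment and their interactions, optionally including the
short-separation-channel TFA phase as an extracerebral nuisance regressor.
Inference choices, where the field has no single convention:

* Wald 95% CIs, estimate ± 1.96·SE.
* t/F reference distributions with a between-within denominator df:
  effects constant within subject use n_subjects − q_between, within-subject
  effects use n_obs − n_subjects − q_within. For a balanced paired design
  this reproduces the paired-t df exactly, and Monte-Carlo calibration at
  n = 38 shows type-I error within 1.5 points of 5% (the naive normal
  approximation is measurably liberal at this size).
* Interaction families are tested jointly by Wald F over their
  coefficients.
* Marginal/conditional R² follow the Nakagawa variance-partition form:
  var(Xβ)/(var(Xβ)+σ²_subj+σ²_res), adding σ²_subj in the numerator for the
  conditional version. AIC is the REML criterion.
* Categorical fixed effects with any level under `min_level_count`
  (default 3) observations are refused rather than silently fitted.
* Non-convergence is recorded on the fit object (or raised on request),
  never swallowed.

## Synthetic data (`synth`)

**Recordings.** ABP = mean level + pulsatile carrier (three harmonics of
the heart rate with relative amplitudes 1/0.4/0.15 — beat-detectable, not
physiologically faithful) + Mayer-wave sinusoid (default 0.1 Hz, 4 mmHg) +
respiratory component (0.25 Hz, 2 mmHg) + broadband Gaussian fluctuation
(1 mmHg SD, treated as physiological and therefore passed to the brain).
Each cerebral channel is the ABP fluctuation passed through a band-wise
transfer function applied by rFFT multiplication — in-band bins get
gain·e^{−i·phase}, out-of-band bins pass unchanged — giving exact analytic
ground truth per band. Scalp contamination is an additive shared scalp
signal (an off-Mayer oscillation plus noise, independent of ABP) scaled so
that its share of channel variance equals the configured extracerebral
fraction (defaults: long 0.2, short 1.0); being additive and incoherent
with ABP it lowers coherence without biasing the transfer estimate. Square-
pulse artifacts with recorded truth masks, slow drift, sensor noise, vitals
traces with excursion schedules and procedure event markers complete the
recording. Everything is bit-reproducible under (config, seed).

Optional per-beat period jitter builds the carrier through a piecewise-
linear cardiac phase, keeping the waveform continuous; it defaults to 0
because frequency-modulated harmonics would blur the exact band placement
the recovery tests rely on.

**Subject tables.** One row per subject × hemisphere × segment with
phase = baseline + group offset + subject random intercept (SD 15°) +
hemisphere effect + per-hemisphere ETCO2 slope × centred ETCO2 + group-
specific segment effect + residual (SD 18°). Default effect sizes mirror
the magnitudes reported for this clinical setting (ischaemic ETCO2 slope
−26.7°/kPa vs contralateral −14.6°/kPa; opposite phase trajectories over
PRE/POST/2H by 90-day outcome group) and are generator settings for
power/calibration studies, not reproduction claims.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no mechanistic cerebral circulation (no
Windkessel, no metabolic feedback, no recanalization haemodynamics), no
heart-rate variability by default, sinusoid-plus-noise LFOs rather than the
unknown true spectral shape, stationary transfer functions within a
recording, and Gaussianity of all noise. Recovery results certify the
estimator chain, not physiology.

## Numerical notes

* Welch with a single exact-length window equals a direct tapered DFT
  cross-spectrum to ~1e-15; this periodogram mode exists for that oracle.
* Band averaging guards bins whose input PSD is below 1e-14 of the band
  maximum (excluded from weights).
* Beat onsets are sample-quantized, then parabolic-refined; recovery versus
  generator truth is within one raw sample at 100 Hz including 3% beat
  jitter.
* Problem sizes used in validation (chosen to keep a desk-scale run):
  recordings of 12–40 min at 50–100 Hz; 18-cell recovery sweep; 20
  randomized recordings for the segment oracle; 1000/500/500/500 replicates
  for the calibration studies.

## Known limitations

* The 10%-variation reference, the artifact criteria, Welch settings and
  the FDR family definition are conventions where the clinical practice the
  package mirrors leaves them unstated; all are explicit configuration.
* Normalized gain requires a caller-supplied output scale (see above).
* The mixed-model df approximation is not Satterthwaite/Kenward–Roger;
  for the balanced designs generated here it is exact or conservative, and
  calibration is verified by simulation, but heavily unbalanced real
  datasets may warrant external refits.
* SNIRF ingestion covers two-wavelength continuous-wave files with inline
  probe geometry; hemisphere assignment from probe x-coordinates is a
  convention of the synthetic fixtures, and real montages should supply
  channel metadata explicitly.
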