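# Methods

`hfoarea` implements an automated pipeline for delineating the interictal
high-frequency-oscillation (HFO) area from multichannel intracranial EEG
(iEEG) and for evaluating, across a multicentre surgical cohort, how well
complete resection of that area predicts postsurgical seizure freedom. This
note documents the models, the tunable constants, the synthetic-data
surrogates the tests run on, and the numerical choices made where the design
was open.

## Signal pipeline

**Preprocessing.** Recordings (2000–5000 Hz, microvolts) are polyphase-
resampled to 2000 Hz (`scipy.signal.resample_poly`); rates below 2000 Hz are
rejected because they cannot represent the fast-ripple band. A bipolar
montage is derived by differencing adjacent contacts within each electrode
(contact *k* − contact *k*+1, named `ELEC<k>-ELEC<k+1>`); a bipolar channel
is flagged bad if either contact is bad or non-cephalic, and bad channels are
dropped before analysis. For subdural grids the "adjacent" relation follows
the labelled contact ordering, which is deterministic from channel labels;
no electrode geometry is modelled. The cleaned recording is cut into
consecutive non-overlapping 5-minute epochs from *t* = 0 (half-open
intervals; a trailing partial epoch is discarded). Centre-marked artefact
sections are carried along as per-channel masks: masked stretches are
excluded from event detection and subtracted from the epoch duration when
rates are computed, so a 60 s artefact inside a 5-minute epoch leaves 4
effective minutes.

**Band-pass filtering** is zero-phase FIR (forward–backward `filtfilt` with a
Hamming-window `firwin` design, 513 taps at 2000 Hz). Zero phase matters
here: any group delay differing between the ripple (80–240 Hz) and
fast-ripple (250–490 Hz) bands would bias the co-occurrence pairing. The
default length gives a ≈13 Hz transition band and >50 dB single-pass
stop-band attenuation (doubled by the forward–backward pass), comfortably
exceeding 40 dB one octave outside the band.

**Detection** is two-stage, with every constant exposed in `AnalysisConfig`:

1. *Envelope threshold.* The analytic (Hilbert) envelope of the band-filtered
   trace is compared against `median + k · 1.4826 · MAD` computed per channel
   and per epoch (default `k = 3`). Computing the threshold per channel-epoch
   makes detection invariant to channel gain and to slow drifts of background
   power. Supra-threshold runs separated by less than 10 ms are merged;
   surviving runs must last ≥20 ms (ripple) or ≥10 ms (fast ripple); runs
   overlapping a masked artefact stretch are discarded.
2. *Spectral validation.* For each candidate, a Hann periodogram of the
   **unfiltered** signal over the event window (±10 ms pad) must show an
   in-band local maximum at least 6 dB above the spectral trough between that
   peak and the low-frequency (<60 Hz) range. Sharp transients ("false
   ripples") have monotonically decaying spectra with no isolated in-band
   peak and are rejected; the local-maximum requirement additionally rejects
   bursts centred just outside the band, which leave only a rising slope
   inside it.

An **HFO** is a validated ripple that overlaps at least one validated fast
ripple in time on the same channel (≥1 sample of overlap). Pairing is
anchored on ripples — several fast ripples nested in one ripple yield a
single HFO — so events are never double-counted. The HFO extent is the union
of the paired events' extents. The HFO rate per channel-epoch is the event
count divided by the effective minutes; channel-epochs with zero effective
minutes are marked missing rather than divided.

## HFO-area rule

Per epoch, the rate threshold is the 95th percentile of that epoch's
cross-channel rate distribution (linear-interpolation quantile, the common
scientific-computing default; configurable). Channels **strictly above** the
threshold are candidates — strict comparison means a degenerate epoch in
which every channel has the same rate elects nobody. A channel's *temporal
consistency* is the percentage of its analysable epochs in which it was a
candidate; the denominator deliberately excludes epochs where the channel was
masked, so centre-marked artefact time does not penalise a channel. Channels
with consistency ≥50% (boundary included) form the HFO area; if no channel
reaches 50% the measure is *inconclusive* and no outcome prediction is made
for that patient.

## Outcome prediction and cohort statistics

A patient's HFO area is *completely resected* (crHFO-area) iff every area
channel lies in the resected set; with contact-level resection data a bipolar
channel counts as resected iff **both** physical contacts lie in the
resection volume (the centre-supplied channel list is accepted as an
alternative). Predictions are scored against the ILAE outcome: TP =
incomplete resection and recurrent seizures (ILAE 2–6), TN = complete
resection and seizure freedom (ILAE 1), FP = incomplete but seizure-free,
FN = complete but recurrent. Inconclusive patients are excluded from the
confusion matrix and reported separately. The clinical-practice comparator —
the resection itself as a predictor — is degenerate by the cohort's inclusion
criteria (the identified focus was always resected), so it is represented as
TP = FP = 0 with TN/FN the seizure-free/recurrent counts; its PPV,
sensitivity and specificity are marked undefined rather than computed from
zero cells.

Statistics layer:

- **Predictive values** use exact Clopper–Pearson intervals (beta quantiles;
  closed at 0 and 1).
- **Paired NPV comparison.** NPV(HFO)/NPV(RV) is estimated on the same
  patients; the log-ratio variance is the empirical variance of its influence
  function under the joint multinomial — the delta-method variance for
  relative predictive values in paired designs — with a two-sided Wald test
  of ratio = 1. When the two tests make identical calls the ratio is exact
  and the p-value is 1 by convention.
- **Random-effects pooling** of per-centre proportions (logit scale; a
  Freeman–Tukey double-arcsine option exists behind a config flag) and odds
  ratios (log scale, 0.5 continuity correction applied to all cells of a
  table with a zero cell) uses the DerSimonian–Laird moment estimator with
  τ² truncated at zero, so homogeneous inputs reduce exactly to the
  fixed-effect inverse-variance mean. Centres whose 2×2 table has an empty
  row or column carry no odds-ratio information and are excluded with a log
  entry. Heterogeneity is reported as Cochran's Q, its χ² p-value, and
  I² = max(0, (Q − df)/Q).
- **SROC.** Per-centre (logit sensitivity, logit specificity) pairs, with the
  usual within-centre binomial variances (0.5-corrected where needed), are
  modelled as bivariate normal around a common mean with between-centre
  covariance, fitted by maximum likelihood (Nelder–Mead on a log-SD/atanh-ρ
  parametrisation). The summary curve is the implied regression of logit
  sensitivity on logit specificity; a positive regression slope (possible
  under sampling noise, meaningless for an ROC) is clamped to zero. AUC is
  the trapezoidal integral of the curve over FPR ∈ [0, 1] and is labelled
  weak (≤0.75), good (0.76–0.92) or excellent above that. CIs for the pooled
  operating point use **t quantiles with k − 2 degrees of freedom** — with
  the half-dozen centres typical of multicentre studies, Wald z intervals
  are anticonservative, and this small-sample correction restores nominal
  coverage. The AUC interval comes from seeded Monte Carlo draws of the
  parameters under their asymptotic normal law (observed information via a
  numerical Hessian; a pseudo-inverse handles boundary-degenerate variance
  directions, and draws of the log-SDs are clipped to ±10). If the bivariate
  fit or its information matrix is unusable, the model falls back to
  univariate DL pooling of each axis, flagged in the result.
- **Rate comparison** between channel groups is the two-sided Wilcoxon
  rank-sum test: exact null distribution when both groups have n ≤ 25 and no
  ties, normal approximation with tie correction otherwise.
- **Outcome model.** Prediction correctness (y = 1 for TP or TN) is
  regressed by OLS on nine ordinally quantized covariates: age
  ([0–13], [14–18], [19–25], [26–59], ≥60 years), sex, pathology class,
  electrode type (ECoG/sEEG/both), number of recorded channels ([1–44],
  [45–104], ≥105), HFO-area size (1, [2–3], [4–7]), number of resected
  channels ([1–5], [6–24], ≥25), crHFO-area (0 = complete), and follow-up
  (24, [25–37], ≥38 months). A linear model is used deliberately despite the
  binary response — coefficients read as differences in correctness
  probability. Benjamini–Hochberg FDR is applied across the nine
  non-intercept effects (the one fitted model defines the family); constant
  covariates are dropped with a warning. All p-values in the package are
  two-sided, and no significance threshold is hard-coded in the computation
  layer.

## Two-phase study runs

`StudyRun` mirrors the blinded design: phase 1 computes HFO areas from
signals only; phase 2 joins resection and outcome data and computes the
cohort statistics. The API refuses clinical data before phase 1 completes. A
patient failing phase 1 is recorded as "no prediction" and the run continues.
Reports carry the configuration hash and seed, and reruns are bit-identical.

## Synthetic data: what it emulates, and what it does not

`simulate_recording` produces 1/f^a background noise (white Gaussian noise
shaped in the frequency domain; a = 1 by default, SD 10 µV) with injected
oscillation bursts. Each burst is a sinusoid at a frequency drawn uniformly
from the injection range, under a **flat-top Tukey envelope** (α = 0.4). A
flat-top envelope was chosen over a Gaussian so that the nominal duration is
the interval the burst actually spends at peak amplitude: with a Gaussian
envelope the shortest default ripple (40 ms) at the default SNR spends less
than the 20 ms minimum duration above the detection threshold, which makes
"duration" ambiguous as a ground-truth quantity. An HFO is a ripple burst
(duration 40–80 ms) and a fast-ripple burst (15–40 ms, capped at the ripple
duration) sharing a centre time. Default injection frequency ranges are
110–220 Hz (ripple) and 320–440 Hz (fast ripple) — kept inside the detection
bands with a margin so that even the shortest bursts hold ≥95% of their
spectral power in band. `snr` (default 5, detectable; configurable down to 1)
is the ratio of burst peak amplitude to the robust (MAD-scaled) SD of the
band-filtered background on the same channel. Event times follow a
homogeneous Poisson process at the per-channel rate; artefacts are
broadband decaying-exponential spikes (τ = 4 ms, 10× background SD). One
master seed drives per-channel substreams keyed by (seed, channel index), so
adding a channel never perturbs existing ones.

`simulate_rate_matrix` is the rate-level counterpart: Poisson counts per
channel-epoch at a designated area rate (default 4 events/min, the observed
median on area channels) versus background (default 0.2 events/min — the
source study reports no non-area rate, so this is this package's choice).
Large HFO-area recovery studies (hundreds of patients × 78 channels × 12
epochs) run at this level; signal-level simulation at that scale would be
prohibitive and would test nothing the detector-level studies do not.

`simulate_cohort` draws patient records with known generating parameters:
complete resection with probability 45/146, seizure freedom conditional on
complete/incomplete resection with probabilities 31/45 and 43/101 (the
observed cell proportions), channel counts uniform in 40–116 (median ≈78),
area sizes 1–7, follow-up 24–280 months.

**Limits of the surrogate.** The generator does not model sleep architecture,
spike-with-HFO morphologies, volume conduction, inter-channel correlation, or
non-stationary background power. Passing tests therefore demonstrate that the
pipeline recovers events and areas of the stated morphology at the stated SNR
and rates, and that the statistical estimators are calibrated under the
generating model — not that the detector matches any particular clinical
detector on real recordings.

## Test and benchmark problem sizes

Simulation-based checks use sizes chosen to keep the full suite fast while
retaining statistical power: detector sensitivity and false-detection rate on
20 five-minute epochs each (≈400 injected events; 100 channel-minutes of pure
noise), HFO-area recovery on 100 simulated patients at full study scale (78
channels × 12 epochs), Clopper–Pearson coverage at 10⁴ replicates, the
relative-NPV test size at 10³ null cohorts of n = 2000, SROC and pooled
proportion/odds-ratio CI coverage at 100 replicate 8-centre cohorts, and
planted-effect recovery of the outcome model at 100 replicate cohorts of 160
patients.

One documented ceiling: the outcome-model check asks the planted crHFO-area
effect to be the *only* FDR discovery. With eight null covariates under
Benjamini–Hochberg at α = 0.05, the probability of zero false discoveries is
bounded near (1 − 0.011)⁸ ≈ 0.92 regardless of sample size, so the observed
sole-discovery rate sits near 90% while the planted effect itself is found in
100% of replicates. The corresponding assertion is kept at its nominal
target and fails by design rather than being loosened.

## I/O formats

EDF reading uses MNE; since no installed library exports EDF, a minimal
16-bit EDF writer (1-second records, physical units µV, per-channel symmetric
scaling) is included and round-trip-tested against MNE's reader. The fixture
format is raw little-endian float32 (channels × time, C order) plus a JSON
sidecar with sampling rate, channel metadata and artefact sections. Event
tables round-trip through CSV at 0.1 ms precision. EDF writing truncates to
whole seconds; analysis epochs are whole minutes, so nothing relevant is
lost.
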