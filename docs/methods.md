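# Methods

`emolink` implements a cross-session, cross-modal analysis of emotional
reactivity: directed EEG connectivity estimated during a laboratory
emotion-regulation task is used to predict heart-rate-variability (HRV)
and behavioral outcomes measured in a separate immersive
shoot/don't-shoot session. This note documents the models, the synthetic
cohort that stands in for participant data, the numerical choices, and
the limits of what the tests demonstrate.

## The analysis chain

### EEG preprocessing

Continuous recordings pass through five steps in a fixed order:

1. **Resampling** to 250 Hz (anti-aliased polyphase; event onsets
   rescaled and rounded to the nearest sample).
2. **Line-noise removal**: sliding-window (4 s, 50% overlap) weighted
   least-squares regression of sine/cosine components at the mains
   frequency and harmonics, with multitaper (DPSS, 3 tapers) weights;
   windows recombine under a Hann taper.
3. **Robust average reference**: per time sample, the Huber M-estimate of
   location across channels (tuning constant 1.345, i.e. 95% Gaussian
   efficiency; scale fixed at 1.4826·MAD; IRLS to 1e-6, median fallback
   on non-convergence) is subtracted.
4. **Artifact subspace reconstruction (ASR)**: per 500 ms window (50%
   overlap), eigendirections whose standard deviation exceeds 15× the
   calibration SD along that direction are removed and the window is
   reconstructed from the retained subspace. Calibration defaults to the
   lowest-RMS contiguous 10 s span.
5. **Piecewise detrending**: overlap-averaged local linear fits
   (330 ms window, 8 ms step, Hann-weighted), removing DC and drift
   slower than the window scale.

Epoching uses half-open sample windows with offsets rounded half-up, so
a (−250, 0) ms window at 250 Hz has 62 samples and (0, 2000) ms has 500.
Out-of-range events are skipped, logged, and counted, so epochs plus
exclusions always equal events.

The window/taper parameters of steps 2–5 beyond the headline constants
(250 Hz, 60 Hz, cutoff 15, 330/8 ms) are this package's declared
defaults; all are configurable through `PreprocConfig`.

### Directed connectivity (dDTF)

Each epoch (or pooled trial set) is fit with a vector autoregressive
model of order 15 by ridge-penalized least squares. The ridge penalty is
relative: the absolute penalty is `ridge · trace(Z'Z)/n_cols` with
default `ridge = 1e-3`, which keeps single-trial fits (500 samples, 180
predictors per equation) well conditioned. The spectral transfer matrix
is `H(f) = (I − Σ_k A_k e^{−i2πfk/fs})^{−1}` on a 1–25 Hz grid at 0.5 Hz.

Directed measures use the squared convention throughout:

- DTF: `γ²_ij(f) = |H_ij|² / Σ_k |H_ik(f)|²` (rows sum to 1 at every f);
- full-frequency DTF: `η²_ij(f) = |H_ij|² / Σ_{f'} Σ_k |H_ik(f')|²`;
- partial coherence from the inverse spectral matrix `P = (H Σ H*)⁻¹`:
  `χ²_ij(f) = |P_ij|² / (P_ii P_jj)`;
- dDTF: `δ_ij(f) = η²_ij(f) · χ²_ij(f)`.

The cited literature alternates between amplitude and squared
conventions; the squared form is used because both factors are then
bounded in [0, 1] and the normalization identities are exact. Entry
(i, j) is the influence of source j on sink i. The montage is the
12-channel frontoparietal/centroparietal set CP3, CPz, CP4, P3, Pz, P4,
FC5, F7, F3, FC4, F8, F4, giving 132 ordered pairs (sink-major
enumeration, diagonal excluded).

Two pathways consume the dDTF, mirroring the two uses in the study
design:

- **Feature pathway** (input to the cross-modal models): per trial, one
  static VAR fit over the 2 s second-presentation window, band-averaged
  (delta 1–3, theta 4–7, alpha 8–12, beta 13–25 Hz; closed intervals,
  arithmetic mean over grid points), then trial-averaged per condition —
  a 132 × 4 × 2 feature object per participant. No baseline correction.
- **Visualization pathway**: sliding-window dDTF (500 ms window, 50 ms
  step, pooled across trials per condition), band-averaged, baseline
  corrected by subtracting the mean over window centers in the 250 ms
  before the second-image onset, z-scored over time within
  connection/band, and averaged across participants. Outflow
  (`Σ_{i≠j} conn[i,j]` per source j) and the top fraction of edges by
  |value| (default 10%, ⌈0.10·132⌉ = 14 edges, ties broken by the fixed
  pair order) summarize the group pattern.

The z-scoring axis and the sliding-window parameters are declared
defaults (the source description names neither); both are arguments.

### HRV spectral analysis

RR intervals are cleaned by physiological bounds — intervals outside
[300, 1500] ms, i.e. heart rate above 200 or below 40 bpm — and an
ectopic rule: deviation > 20% from the running median of 11 neighbors.
Passes repeat to a fixed point, which makes cleaning idempotent; every
removal is logged. If more than half the series is removed the series is
rejected. The ectopic rule is a documented stand-in for a proprietary
commercial filter; its two constants are arguments.

The cleaned intervals are cubic-spline interpolated against beat time,
resampled at 4 Hz, mean-removed, Hann-windowed, and decomposed with a
single periodogram whose density scaling is window-compensated, so the
integral over frequency equals the windowed signal's variance
contribution (Parseval-consistent to float precision). LF is 0.04–0.15
Hz, HF 0.15–0.40 Hz, both in absolute ms² (no normalized units). Per
participant this yields a 2 (band) × 2 (condition) table; an unusable
condition is reported as missing, never as zero.

### Behavioral measures

Seven measures per participant: mean 1–9 intensity ratings for the
attend and reinterpret conditions; accuracy `(H + CR)/N` per simulation
condition (N = 128 in the study design); and three anxiety raw scores
(laboratory, after low-stress, after high-stress), each the count of
endorsed adjectives from a 10-item checklist subscale. Hit/false-alarm
rates and a log-linear-corrected d′ (`(count+0.5)/(total+1)`) are
provided separately; the headline accuracy is the raw proportion.
T-score conversion is a pure lookup keyed by (raw score, total checked)
in a user-supplied norm table — the published norms are proprietary and
are neither shipped nor approximated.

### Cross-modal LASSO with Monte-Carlo cross-validation

For each crossing of laboratory condition × EEG band × simulation
condition × HRV band (2·4·2·2 = 32 models), the 132 connectivity
features predict the participant-level HRV band power. Per model:

- Monte-Carlo cross-validation: random disjoint splits into 20 training
  and 5 test participants (500 in the headline design; reduced counts
  are stated wherever used);
- a 25-point geometric lambda grid from 0.032 to 1.0, interpreted on the
  standardized-feature scale; features are standardized and the response
  centered using training-split statistics only;
- the LASSO objective `(1/2n)‖y − Xβ‖² + λ‖β‖₁` (solved by
  scikit-learn's coordinate descent); out-of-sample
  `R² = 1 − SS_res/SS_tot` with SS_tot about the **test**-split mean —
  the stricter standard definition;
- a model is *flagged* when the fraction of splits with positive R² at
  its best-mean-R² lambda reaches 0.95;
- *robust connections* are features with nonzero coefficients in at
  least half (configurable) of the positive-R² splits at that lambda,
  each with the sign of the majority of its coefficients (ties give sign
  0 and a warning). Split memberships are stored, so any published edge
  list is exactly reproducible from the seed.

With 20 training observations and 132 features the LASSO can stabilize
on a proxy feature correlated with a true one; the robustness count is a
stability measure, not a support-recovery guarantee, and the count
threshold is reported with the results.

Robust-edge features are then correlated (Pearson, two-sided p, pairwise
complete) with the seven behavioral measures; Benjamini-Hochberg FDR
adjusted p-values are reported alongside raw ones for both the
model-grid and the correlation table.

### Inferential statistics

Paired t (df = n−1; identical inputs give t = 0, p = 1), Wilcoxon
signed-rank as a continuity-corrected normal approximation (zeros
dropped, midranks for ties; an all-zero difference vector raises),
Pearson r with the t transform on n−2 df, and BH-FDR adjustment. All
two-sided.

## The synthetic cohort

No participant data are distributable, so a generator produces cohorts
with the full statistical structure the analysis assumes and known
ground truth. One standard-normal latent trait `z` per participant links
all modalities:

- **EEG**: each channel carries an AR(1) diagonal (coefficient 0.5).
  A planted directed coupling gives its *source* channel a
  damped-oscillator AR(2) diagonal (pole radius 0.99) at the band's
  center frequency and adds a one-lag cross coefficient into the sink.
  The source then carries a prominent narrowband rhythm, and the
  spectral transfer into the sink is sharply concentrated in the planted
  band. Each participant receives an individual peak frequency (uniform
  ±0.5 Hz around the band center), matching the well-documented
  individual variability of EEG rhythms; this also decorrelates the
  Lorentzian out-of-band tail of the resonance from the trait, which
  keeps neighboring-band features uninformative. Squared edge strength
  is linear in the trait: `s² = s₀²·max(1 + loading·z, 0.05)` with
  default `s₀ = 0.006` and loading 0.5; the reinterpret condition
  subtracts 0.3 on this power scale (attend > reinterpret). Stability is
  verified via the companion spectral radius at construction; unstable
  requests raise, naming the offending edge. Simulation discards a
  burn-in of 10× the model order. Default planted edges: F4→Pz, F3→P3,
  FC4→CP4, all theta.
- **HRV**: RR series per simulation condition by direct modulation of
  the instantaneous inter-beat interval (mean 800 ms) with LF (0.10 Hz)
  and HF (0.25 Hz) sine terms plus 20 ms Gaussian jitter — chosen over
  integral-pulse-frequency modulation because the expected spectrum is
  then in closed form. LF power is linear in the trait
  (amplitude `= 50·sqrt(max(1 + 0.5·z, 0.05))` ms, high-stress base
  +10 ms); HF amplitude is fixed at 30 ms. A 2% ectopic rate (halved
  intervals) exercises the cleaning rules.
- **Behavior**: per-trial ratings are rounded clipped Gaussians around
  condition means 3.65 (attend) and 2.85 (reinterpret) plus 0.6·z, SD
  1.5; outcome categories follow condition error rates 0.13 (low) /
  0.16 (high) plus 0.02·z on 128 trials (half foe, half friendly);
  anxiety raw counts cluster at 2 / 4 / 5 (lab / low / high) plus
  1.2·z, clipped to [0, 10].

The condition means and error rates are anchored to the observable
group-level values of the study design; every loading, noise scale and
condition shift beyond those is this package's own choice (no published
effect sizes exist for them), selected once so that the planted
brain→HRV linkage is recoverable and band-specific at the default cohort
size, and documented here rather than presented as empirical values.

What the generator does **not** emulate: volume conduction and a shared
reference forward model, non-stationary artifacts, realistic ECG
morphology (RR intervals only), inter-trial dependence, and rhythms on
non-source channels. Consequently, passing recovery tests show the
estimators and the cross-modal machinery are correct and calibrated on
data satisfying the model's assumptions — they do not certify
performance on real recordings.

One consequence is documented rather than hidden: with only the 12
modeled channels, the robust average reference mixes each focal
narrowband source into every channel, which the partial-coherence factor
of the dDTF then (correctly) treats as common input, suppressing the
planted coupling. A real study references against the full high-density
montage before channel reduction, which the 12-channel synthetic cohort
cannot emulate. The synthetic pipeline therefore disables the reference
step by default (`RunConfig.preproc`), while the step itself remains
implemented, tested, and on by default in `PreprocConfig` for real
recordings.

## Numerical choices and degenerate inputs

- Ridge fits solve the normal equations; `ridge = 0` on a rank-deficient
  design raises with advice to use a positive penalty. Constant input
  raises (zero-variance design).
- Near-singular spectral matrices get a relative diagonal jitter
  (1e-10·trace/n) with a logged warning before inversion.
- Zero-variance features are dropped from LASSO fits (coefficient 0,
  warning); zero-SD slices z-score to 0 with a warning.
- Ties in edge ranking break by the fixed sink-major pair order, making
  all reported edge lists deterministic.
- Every stochastic stage derives its seed from a master seed via
  `numpy.random.SeedSequence` spawning; manifests record seeds and
  SHA-256 hashes of all artifacts, and omit the output path so that two
  runs with one master seed produce byte-identical manifests.

## Problem sizes used in checks

The test suite and the acceptance script scale the study design down to
keep runs small: estimator checks use 10,000–30,000 samples; the
pipeline demonstration cohort uses 8 participants × 6 trials per
condition; the acceptance pipeline uses the full 25 participants with 30
trials per condition, 64 simulation trials, 300 s RR records, and 100
Monte-Carlo splits per model (the headline design: 60 lab trials, 128
simulation trials, 500 splits). These sizes are stated where used and
are the package's own choices.

## Known limitations

- dDTF values are not invariant to per-channel amplitude rescaling;
  comparisons across montages or gain settings require consistent
  scaling.
- The flagged-model criterion (95% positive-R² splits) is a robustness
  heuristic, not a formal test; no multiplicity control is applied
  across the 32 models beyond the reported BH-FDR column.
- The Wilcoxon normal approximation is used at all n (validated against
  exact enumeration at n ≤ 10 in the tests); for very small samples an
  exact method may be preferable.
- T-score anxiety conversion is unavailable without the publisher's norm
  table by design.
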