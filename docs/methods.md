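# Methods

## Scientific setting

Deep sedation in the neuro-ICU (barbiturates, propofol) produces EEG
*burst suppression*: alternation between high-amplitude bursts and
near-isoelectric suppression epochs. `sibskit` quantifies the depth of
sedation-induced burst suppression per patient and relates it to global
outcome after moderate-to-severe traumatic brain injury, with the working
hypothesis that deeper suppression (higher maximum BSR) is associated with
*better* chronic outcome once overall behavioural recovery (maximum GCS) is
controlled for.

## Burst suppression ratio

For a 10-minute, 13-channel EEG section the signal is re-referenced to the
cross-channel average, band-pass filtered 0.5–45 Hz (zero-phase 4th-order
Butterworth; forward-backward application avoids latency-shifting
suppression boundaries), rectified, and binarized per channel at a voltage
threshold θ (default 1 μV, strict inequality `|x| < θ`; a sample exactly at
θ counts as non-suppressed). The per-sample modal value across channels
collapses the binary matrix to one consensus series, and

    BSR = mean(consensus over unmasked samples) ∈ [0, 1].

BSR is kept continuous throughout; no burst-suppression category is ever
assigned. Artifact cleaning is out of scope: cleaned-out stretches enter as
a boolean bad-sample mask, and a section more than 50% masked (configurable)
is flagged unusable. With 13 channels the majority vote has no ties; for
even channel counts a tie resolves to suppression (documented, arbitrary).

Threshold calibration diagnostics follow two criteria: a good threshold
(1) yields high BSR (> 0.5 by default) only for sections recorded at the
floor of responsiveness (GCS 3), and (2) yields BSR values that track the
base-10 log of the Pearson (non-excess) kurtosis of the pooled voltages.
Kurtosis is pooled across channels and samples; the Gaussian reference is
3 (log10 ≈ 0.477), and a burst-suppression mixture with suppression
fraction f has kurtosis ≈ 3/(1−f) — rising in f until the fully isoelectric
limit, where the absence of bursts collapses the signal back to
near-Gaussian noise and low kurtosis. Cross-channel agreement of the binary
indicators is summarized by the one-way random-effects single-measure
ICC(1,1), treating samples as targets and channels as raters — the
least-assumption ICC variant, recorded in the result metadata; the variant
choice matters little for near-perfect agreement.

## Section selection

EEG sections target windows of minimal behavioural responsiveness: GCS
assessments are sorted ascending by (score, timestamp) — earlier timestamps
first on ties, a deterministic convention that favours earlier sedation
epochs — the lowest seeds the selection, and each assessment in sorted
order is added iff its timestamp is ≥ 24 h from every selected one.
Sections start at the selected timestamp (configurable). The greedy rule is
provably equivalent to choosing, among all maximal spacing-feasible subsets
of assessments, the one with the lexicographically smallest (score, time)
sequence; the test suite checks this equivalence exhaustively for series of
up to 8 assessments.

## Multi-model inference

GOSe is dichotomized at its sample median: discharge 1–2 vs. 3–4
(favourable = GOSe ≥ 3, 20/12 in the packaged cohort) and chronic 1–4 vs.
5–8 (15/15 of 30 complete cases; the 2 patients without chronic assessments
are dropped, complete-case). All 16 logistic models over subsets of
{max BSR, max GCS, sex, age} (intercept always included) are fitted by IRLS
(convergence tolerance 1e-10); perfect separation is flagged, not raised.
Models are ranked by

    AICc = −2·logLik + 2k + 2k(k+1)/(n−k−1),

and Akaike weights exp(−Δ/2) are normalized over the Δ ≤ 5 confidence
window (models outside carry weight 0; with Δ ≥ 13 outside the window on
this cohort, window-normalization is numerically indistinguishable from
all-model normalization).

Averaged parameters use *conditional* (subset) averaging: a term's estimate
averages over only the window models containing it, weights renormalized
within that subset. This choice is verifiable from the published averaged
sex estimate, which is reproducible only under conditional averaging. The
unconditional SE pools within-model variance and between-model spread,
Σᵢ wᵢ √(varᵢ + (βᵢ − β̄)²); the adjusted SE scales each model's variance by
(t₀.₉₇₅,ₙ₋ₖ / z₀.₉₇₅)² before pooling — a small-sample df correction whose
exact original formulation is not published, so this is the one reported
column not guaranteed to reproduce numerically. z = |β̄|/adj SE with
two-sided normal p; no multiplicity correction.

Sex is coded M = 0 / F = 1 (likelihoods, AICc, weights and other
coefficients are invariant to this). Ages are available only as bins, so
age enters as the bin midpoint (21.5, 32.5, 47.5, 62.5, 77.5 years);
model rows containing age are therefore approximations and are validated
qualitatively (sign, magnitude), never exactly.

## Mediation

Whether BSR transmits a sedative effect to outcome is assessed in the
potential-outcomes framework with the quasi-Bayesian Monte-Carlo algorithm
(default 1000 parameter draws): a mediator model (linear for the continuous
max BSR, logistic for a binary medication flag) and an outcome logistic
model, both with the max-GCS covariate and no treatment-mediator
interaction by default; parameters are drawn from each model's asymptotic
normal, potential mediators are simulated with residual error (or Bernoulli
draws), and ACME/ADE/total effects are averages of potential-outcome
differences on the probability (risk-difference) scale, with percentile
intervals and simulation p-values from the per-draw averages. Medication is
coded as given on the day of the patient's maximum BSR. The published
finding is a null (no significant mediation), so validation is
calibration-based — nominal 95% ACME intervals cover zero at least ~95% of
the time under a no-mediation generator — plus agreement in
non-significance on the packaged cohort. A bootstrap variant is not
implemented; the quasi-Bayesian approximation is the 1000-draw default of
the standard approach.

## Synthetic-data generator

The generator realizes exactly the statistical structure the analysis
assumes, and no more:

* **State process** — a common two-state alternating-renewal path with
  log-normal dwell times (burst mean 4 s, log-space σ = 0.5; suppression
  mean set to `4·f/(1−f)` s so the long-run suppression fraction equals the
  target f). Log-normal is the conventional positive right-skewed choice;
  no published dwell statistics exist for this setting.
* **Amplitudes** — suppression: zero-mean Gaussian noise, σ = 0.2 μV, so
  rectified amplitudes stay below 1 μV essentially surely (5σ);
  burst: per-channel band-limited (0.5–30 Hz) noise, σ = 20 μV, plus a
  rectified-amplitude floor of 15% of the burst σ (3 μV at default). The
  floor is the generator's state-separation contract: a plain Gaussian
  burst spends ≈ 4% of samples below 1 μV, which would leak into per-channel
  suppression fractions and channel disagreement; real bursts are not
  Gaussian near zero, and the floor emulates their sustained amplitude.
* **Channel structure** — each channel copies the common state except at
  independently jittered samples (default probability 0.001, zero when the
  path is constant, since jitter models asynchrony around transitions).
  The default is derived analytically: independent flips at rate ε give a
  population ICC of f(1−f)(1−2ε)²/(f(1−f)(1−2ε)² + ε(1−ε)), so ε = 0.001
  yields ICC ≈ 0.996–0.998 at mid prevalence, matching the near-perfect
  channel agreement seen clinically; ε ≥ 0.005 could not.
* **GCS trajectories** — four assessments per simulated day, scores 3–6
  inside declared sedation windows and 7–15 outside.
* **Cohorts** — per patient: max GCS ~ uniform {3..15}; target max BSR from
  a mixture (25% Beta(5, 1.5) deep suppression, else Beta(0.4, 4)) chosen
  to mirror the observed bimodal BSR distribution; binary outcomes from
  logistic(−13 + 8·maxBSR + 1·maxGCS), the magnitude regime of the chronic
  estimates; GOSe scores placed on the matching side of each median-split
  cutoff so dichotomization recovers the generated outcome exactly.
  EEG sections are attached only on request (`eeg=True`); large parameter-
  recovery simulations use the recorded ground-truth BSR directly, since
  re-deriving it from simulated EEG adds cost but no information (BSR
  recovery is tested separately).

What the generator does **not** emulate: oscillatory spectra, artifacts,
electrode drop-out, recording discontinuities, or any physiological
coupling between sedation dosing and EEG. Passing tests therefore
demonstrate correctness of the *algorithms* under the assumed structure,
not robustness to real clinical EEG.

All randomness flows from one integer seed through `numpy.random.default_rng`
child streams; outputs are byte-identical under a fixed seed and embed the
seed and a configuration hash.

## Numerical choices and degenerate inputs

* Logistic fits: statsmodels GLM/Binomial IRLS, tolerance 1e-10, ≤ 100
  iterations; separation flagged via fitted probabilities within 1e-6 of
  the outcomes or |β| > 1e3. Non-finite AICc excludes a model from ranking
  as a per-model error entry.
* AICc requires n > k + 1; intercept-only closed forms (ln(p/(1−p)),
  n·entropy) are used as analytic test anchors.
* Flat signals: kurtosis and ICC return `None` (undefined) rather than
  raising; zero usable samples after masking raise.
* Chi-squared: Pearson, 1 df, no continuity correction; zero margins raise.
* Reduced-rate synthetic runs cap the band-pass upper edge at 0.45·fs.

## Problem sizes

Defaults reproduce the published analysis exactly (n = 32/30 patients,
10-minute 256 Hz sections, Δ ≤ 5, 1000 mediation draws). Simulation-based
validation uses 20 seeds at full section scale for BSR recovery, 200
replicates of n = 500 cohorts for parameter recovery, and 100 replicates of
n = 200 tables for mediation calibration — sizes at which Monte-Carlo error
is well below the tested tolerances.

## Known limitations

* Age-bin midpoints cannot reproduce model rows fitted to exact ages; those
  rows are checked qualitatively only.
* The adjusted-SE small-sample formula is a documented reconstruction, not
  a published formula.
* EDF export is not provided (text matrices + JSON sidecars are the native
  format; EDF reading is available when `mne` is installed).
* The cohort is small (n = 32) and observational; the package reproduces
  the analysis, it does not strengthen its causal claims.
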