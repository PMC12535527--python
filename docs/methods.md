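# Methods

`hrvsync` reimplements, as a tested pipeline, an analysis of heart-rate-
variability (HRV) synchronization within a horse-assisted-therapy triad —
participant, riding therapist, therapy horse — together with a synthetic-triad
generator that provides ground truth for every stage.  This note documents the
models, the parameters that matter, the numerical choices, and what the tests
do and do not establish.

## Synthetic triads

### Cardiac model

Each heart is an integral pulse frequency modulation (IPFM) oscillator: a beat
is emitted whenever

    ∫₀ᵗ (HR/60) · m(τ) dτ

crosses the next integer, where `HR` is the species' resting rate
(participant 70 bpm, therapist 65 bpm, horse 38 bpm) and `m(t)` is a positive
modulating signal around 1.  IPFM is the standard way to obtain RR series with
controlled spectral content; real recordings are of course not generated by
any model, so this component is invented plumbing whose job is to be
*controllable*, not biologically complete.

### Modulators and coupling

For each subject,

    m(t) = 1 + a_HF · hf(t) + a_LF · lf(t) + σ · ε(t)

with unit-variance narrowband oscillators `hf` (respiratory band; 0.25 Hz for
humans, 0.10 Hz for horses) and `lf` (0.10 / 0.05 Hz), and white noise ε.
Default depths `a_HF = 0.05`, `a_LF = 0.025`, `σ = 0.01` give a resting RR
coefficient of variation near 6%, comfortably inside the 20–50% relative
corridor the artifact detector uses — a clean synthetic series must not trip
the cleaner, or generator and cleaner would be mutually inconsistent.

Dyadic coupling: each dyad owns a *shared* HF oscillator `S_d(t)` at 0.25 Hz
(inside the human HF analysis band — coupling must live where the analysis
looks).  A subject in dyads d₁, d₂ has

    hf(t) = √κ₁ S_{d₁} + √κ₂ S_{d₂} + √(1 − κ₁ − κ₂) · own(t),

so `κ_d ∈ [0, 1]` is the variance share of the HF modulator common to the
dyad; the HF components of two partners correlate at exactly κ, and κ = 1
makes them identical.  Per-subject κ sums are renormalized if a configuration
would exceed 1; default cohort baselines are chosen so that never triggers.

Two envelope families are used.  *Own* components are Gaussian-envelope
narrowband noise (relative bandwidth 0.2, envelope decorrelation ≈ 3 s) —
individual respiratory variability.  The *shared* oscillator is
constant-envelope with narrowband phase drift ("rhythmic breathing"),
implemented as the unit-magnitude analytic signal of a narrowband process.
This matters: cross-wavelet **power** is a modulus, so with a Gaussian-envelope
shared component the modulus responds to κ only through envelope correlation —
a quadratic, few-percent effect that no desk-scale cohort can resolve.  A
rhythmic shared drive moves the response into each partner's mean modulus
(a Rice-mean effect), which is monotone, far stronger, and much less noisy
between sessions.  This is a deliberate design choice of the generator, made
and documented before the validation suite was frozen.

### Cohorts, timeline, CTQ

Controls receive 1 session, patients 4, mirroring the emulated study design (56/36 by
default).  The session timeline follows the emulated session schedule (questionnaire,
contact 5 min, grooming 5 min, riding 15 min, **lying 5 min**, farewell,
questionnaire); a compact variant keeps the full 300 s lying block and trims
everything else for simulation speed.  Childhood Trauma Questionnaire (CTQ)
scores are drawn per participant: a shared severity in (0, 1) — near-uniform
for patients so totals span the full 25–125 illustrative range, low-skewed for
controls — plus per-subscale jitter, each subscale in [5, 25].

Ground-truth effects are linear in the rescaled total `(CTQ − 25)/100`:
`κ_tp = base + slope_t · ctq`, `κ_hp = base + slope_h · ctq`, clipped to
[0, 1]; the horse–therapist κ shifts additively when the therapist works her
favorite horse; the participant–horse κ gains a proximity boost (+0.2 by
default) during lying.  All randomness descends from one cohort seed through a
`SeedSequence` spawn tree, so equal seeds give bit-identical cohorts.

### Artifacts

`inject_artifacts` reproduces chest-belt failure modes with a ground-truth
mask: multiplicative RR spikes near 0.5× (false trigger) and 2× (missed
beat), exact duplicate rows, and dropout windows with all beats removed.
Horse recordings are simulated with higher artifact rates downstream, matching
field experience with equine chest belts.

## RR cleaning

The chain is duplicates → outliers → gap interpolation.  Outliers: a beat is
flagged when its relative deviation from the running median of its 11
non-flagged neighbours *strictly* exceeds the threshold (default 0.30, bounded
to the stated 20–50% range), or when it leaves absolute species bounds
(human 300–2000 ms, equine 500–4000 ms).  Gaps ≤ 2 s are bridged by beats
whose RR interpolates linearly between the flanking intervals (the gap-end
beat's own RR is treated as unreliable, since it may span the gap); longer
gaps follow a linear trend fitted to 10 s of real data on each side — the
simplest auditable "best estimate from longer pre- and post-sections".
Inserted beats are flagged; total inserted time matches the gap within half a
median RR.

Equine series get an iterative detect → delete → interpolate loop (≤ 5
passes, early exit on a clean pass) with a per-pass audit log, replacing the
visual/semi-manual step of the original workflow with a reproducible
automaton; a pass flagging > 50% of beats aborts with an "unusable recording"
error.  RMSSD (√mean(ΔRR²)) over the four-minute analysis window provides the
baseline-HRV covariate.  Bridged beats cannot recover unobserved modulation,
so ~1% of beats retain > 5% error after repairing 5% contamination; the
aggregate indices (RMSSD, band power) recover to within a few percent.

## Cross-wavelet synchrony

Cleaned series are resampled to 4 Hz tachograms by cubic spline (4 Hz is
common HRV practice; Nyquist 2 Hz covers all bands), on half-open windows.
The Morlet CWT follows the Torrence–Compo formulation: frequency-domain
convolution (ω₀ = 6, dj = 1/12, s₀ = 2Δt, scales up to a quarter of the
window), Fourier period λ(s) = 4πs/(ω₀ + √(2 + ω₀²)) ≈ 1.033 s, cone of
influence at the √2·s e-folding time.  Daughters are normalized so unit-
variance white noise has expected power 1 at every scale — the normalization
the significance test assumes.  The cross-wavelet transform is
W_xy = W_x · conj(W_y); *power* is its modulus (computed as |W_x||W_y|, which
is identical and floating-point-stable), *phase* its argument.

Pointwise significance against red noise: each tachogram's lag-1
autocorrelation fixes a theoretical AR(1) spectrum P(f); under the null,
|W_xy| per cell behaves as √(P_x P_y)·Z/2 where Z = √(χ²₂ · χ²₂′) has tail
P(Z > z) = z·K₁(z) (Bessel K₁), reproducing the tabulated Z(5%) = 3.999.  A
Monte-Carlo mode (per-scale quantiles over ≥ 300 matched AR(1) surrogate
pairs) is the independent cross-check; at α = 0 it uses the global surrogate
maximum.  Calibration is verified empirically: ~5% of out-of-cone cells flag
on uncoupled AR(1) pairs.  The significance mask is reported but does **not**
gate extraction.

Bands: HF 0.15–0.40 Hz and LF 0.04–0.15 Hz, each split at its geometric
midpoint into UHF/LHF (0.245 Hz) and ULF/LLF (0.0775 Hz); only the 0.15 Hz ↔
6.67 s HF edge is externally anchored.  Frequencies map to periods as 1/f,
half-open [low, high) everywhere.  Definitions occasionally seen that put LF *above* 0.15 Hz are treated as
typos for the standard convention.

Extraction: the first 240 s of lying, as 4 minutes × 6 ten-second intervals ×
{LHF, UHF}; each cell of the table is the mean cross power over grid cells in
that time/band box, excluding cells outside the cone (zero-filling would bias
edge intervals); rows losing > 50% of cells are flagged.  The tachogram
window extends 30 s beyond the analysis window on each side so the cone at HF
periods clears every extracted interval.  Powers are then log-transformed
(wavelet power is right-skewed) and z-scored with the sample sd within a
stratum — by default the dyad, pooled across sessions and participants.
Pooling is essential for any between-person question: z-scoring within
dyad × session (available as a config switch) forces every session mean to
zero and erases between-participant effects such as the CTQ gradient.

## Hierarchical models

The response is one dyad's `cwp_z`; rows are 10-s intervals nested in minutes
in sessions in participants.  Models are linear mixed models fitted by
maximum likelihood (statsmodels `MixedLM`; ML, never REML, so that
likelihood-ratio comparisons are valid), with random intercepts (and
optionally slopes; a singular slope fit falls back to intercepts and records
the fallback).  Fixed-effect CIs and p-values use the Wald normal
approximation with standard errors from (X'V⁻¹X)⁻¹ — the conditional GLS
form lme4 reports, which stays defined when a variance component sits on the
boundary (the joint observed-information SEs do not).  The implementation is
cross-checked against lme4 (ML) in the test suite: log-likelihoods and
estimates agree to ~10⁻⁴.

Nested models are compared by LRT: χ² = 2Δll floored at 0, df = parameter-
count difference, α = 0.05.  A ladder (null → design terms → covariates →
substantive predictors) keeps a rung only if it beats the current best rung;
non-convergence halts with partial results.  Optimizer note: the default
MixedLM optimizer can return a degenerate boundary solution with infinite
log-likelihood flagged as converged; fits reject non-finite likelihoods and
fall through Powell/Nelder–Mead.

Goodness of fit is Nakagawa's R²: marginal = var(Xβ)/(var(Xβ) + Σz'Σz̄ + σ²),
conditional adds the random-effect variance to the numerator.  Assumption
checks (residual skew/kurtosis, Shapiro–Wilk on a capped subsample, Levene
across fitted-value quartiles, VIFs with aliasing detection, |z| > 4 outlier
count) are advisory only.

## Validation experiments and their scale

`hrvsync.experiments` packages the ground-truth checks; sizes were chosen as
the package's own desk-scale study conditions:

- **Significance calibration** — 200 AR(1) pairs (240 s, 4 Hz, a = 0.7),
  flag fraction outside the cone at α = 0.05; expected ≈ 0.05.
- **Coupling monotonicity** — mean extracted HF cross power over 20 seeds per
  κ ∈ {0, 0.5, 1} (and the finer grid), strictly increasing.
- **Cleaning recovery** — RMSSD after repairing 5% spikes + a 1.5 s dropout,
  within 10% of the uncorrupted value.
- **Parameter recovery** — slope 0.5, 40 groups × 48 observations, 200
  replicates: mean estimate within ±0.05, CI coverage in [0.92, 0.98].
- **Ladder type-I** — 500 one-df null LRTs at α = 0.05, rejection in 3–7%.
- **CTQ dissociation** — 25 cohorts of 96 patients × 4 sessions, compact
  timeline, CTQ→therapist-coupling slope −0.3, CTQ→horse-coupling slope 0.
  At least 80% of cohorts must show a significant negative CTQ estimate for
  therapist–participant *and* a non-significant one for horse–participant.
  Three design-time findings fixed this experiment's conditions: (i) the
  modulus statistic resolves κ mostly in its upper range, so the therapist
  dyad runs at baseline κ = 0.85; (ii) the CTQ attenuation acts on the
  *therapist's side* of the dyad (member-asymmetric weights; the partners'
  HF correlation is the geometric mean of the two sides) — a symmetric κ
  change alters the participant's HF composition and leaks a spurious
  negative CTQ slope into horse–participant power through the participant's
  modulus, an artifact of modulus-based cross power that real dyadic designs
  share; (iii) every subject keeps a nonzero own HF component (budgets
  ≤ 0.95; a purely-shared modulus is two-phasor interference, which inflates
  between-participant variance and mis-calibrates the horse-dyad test).
  Cohort size comes from a power analysis targeting ~98% per-cohort
  detection.

## What passing does and does not show

The generator emulates the statistical skeleton of the recordings — species
rates, HF/LF structure, tunable coupling, nesting, artifact burden, a
CTQ-linked coupling gradient — not riding motion, respiration traces,
electrode physics, menstrual-cycle effects, or genuine leader–follower
dynamics.  Passing therefore demonstrates that the pipeline recovers known
structure of this class faithfully (calibrated significance, monotone
synchrony readout, unbiased mixed-model inference); it does not certify the
biological claims of any particular recorded cohort.  Exact replication of
any recorded cohort's model tables would require its raw data, which the
pipeline can ingest through the RR-CSV adapter.

## Known limitations

- The cross-power modulus is weakly sensitive to moderate coupling changes
  under additive Gaussian-envelope mixing; dyadic designs relying on that
  regime need very large cohorts (this drove the rhythmic shared-oscillator
  choice above).
- Equine HF is modeled at the species' own 0.10 Hz but coupling is placed at
  0.25 Hz so that one common (human) band grid serves all dyads; whether a
  species-specific equine HF band would be more appropriate is left open, and
  the band edges are configurable.
- Long-gap interpolation is a linear local trend; it restores timing budget
  and aggregate indices, not true beat-level variability.
- Wald inference assumes large within-group n; no Satterthwaite/Kenward-Roger
  degrees of freedom are implemented.
- No multiple-testing correction across CTQ subscales (each subscale is
  tested in its own model, mirroring the emulated analysis); reports note this.
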