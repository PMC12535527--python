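# hrvsync

Cross-wavelet heart-rate-variability (HRV) synchrony in horse-assisted-therapy
triads: RR-interval cleaning, Morlet cross-wavelet power with red-noise
significance, band-wise 10-second synchrony extraction during the "lying"
segment, and hierarchical mixed-model ladders over the resulting table — plus
a synthetic-triad generator with known, tunable coupling so every stage can be
verified against ground truth.

## The problem

When a participant lies prone on a standing therapy horse, the respiratory
(high-frequency, parasympathetic) components of the two heartbeats can align;
the same question arises for the riding therapist. Quantifying such dyadic
physiological synchrony from beat-to-beat (RR) recordings of all three
partners, and asking what predicts it — the other dyad's synchrony, the
therapist's favorite horse, early-life adversity (Childhood Trauma
Questionnaire, CTQ) — requires a chain of methods:

1. **Cleaning** — duplicate removal, relative-threshold (20–50%) outlier
   detection against a running median, gap interpolation (≤ 2 s bridged from
   the flanking intervals, longer gaps by a local linear trend), and an
   iterative automatic pass for the error-prone equine recordings; baseline
   HRV as RMSSD = √mean(ΔRR²).
2. **Cross-wavelet power** — tachograms at 4 Hz, Morlet CWT per
   Torrence & Compo (ω₀ = 6, Fourier period λ = 4πs/(ω₀+√(2+ω₀²))), cross
   transform W_xy = W_x·conj(W_y), pointwise significance of |W_xy| against
   the product of the two AR(1) background spectra (the √(χ²·χ²) tail
   z·K₁(z) = α, so Z(5%) = 3.999), cone-of-influence masking, and phase
   arrows (rightward = in-phase).
3. **Band extraction** — HF (0.15–0.40 Hz, i.e. periods below 6.67 s) split
   into LHF/UHF at 0.245 Hz; mean in-cone cross power per 10-s interval × 4
   minutes of lying; log + z-scored within dyad.
4. **Models** — linear mixed models (maximum likelihood) of the z-scored
   power with 10-s intervals nested in minutes, sessions, and participants;
   nested models compared by likelihood-ratio ANOVA at α = 0.05 along a
   ladder (null → design terms → covariates → predictors); Nakagawa marginal
   and conditional R².

See `docs/methods.md` for assumptions, defaults, and design choices.

## Worked example

Simulate a small cohort (4 controls, 2 patients → 12 sessions), clean it, run
the cross-wavelet stage, and fit the model ladder:

```bash
cat > demo.yaml <<EOF
n_control: 4
n_patient: 2
seed: 11
outdir: demo_run
EOF
hrvsync all --config demo.yaml
```

which ends with (abridged):

```
band-power rows: 1728
                       count  mean  std    min    ...    max
horse-participant      576.0   0.0  1.0 -2.977    ...  2.995
horse-therapist        576.0  -0.0  1.0 -3.960    ...  2.986
therapist-participant  576.0  -0.0  1.0 -3.205    ...  2.917

ladder_horse-participant.csv:
            model  df    loglik        aic     chi2       p   kept
0  intercept-only   3 -816.8082  1639.6163      NaN     NaN   True
1          design   7 -806.1918  1626.3835  21.2328  0.0003   True
2      design+ctq   8 -805.9022  1627.8043   0.5792  0.4466  False
```

Reading this: each of the 12 sessions contributes 24 ten-second intervals × 2
HF bands × 3 dyads = 144 rows (1728 total); z-scored power has mean 0 and
unit variance within each dyad by construction. For the horse–participant
response, adding the design terms (minute, band) improves fit
(χ² = 21.2, p < 0.001) while adding the CTQ total does not (χ² = 0.58,
p = 0.45) — as expected here, since this demo cohort was generated without a
CTQ→coupling effect. `hrvsync sync --plot` additionally renders a
cross-wavelet power map (period × time, significance contours, cone hatching,
phase arrows) for the first session.

The same machinery is exposed as a library:

```python
from hrvsync import experiments
df = experiments.kappa_hf_power(kappas=(0.0, 0.5, 1.0), n_seeds=20, seed=3)
print(df.groupby("kappa")["hf_power"].mean())
# kappa
# 0.0    5.0654
# 0.5    5.2376
# 1.0    6.2438
```

— extracted HF cross power rises monotonically with the generator's true
shared-variance fraction κ.

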