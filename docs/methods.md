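# Methods

`nirsconn` implements a resting-state fNIRS functional-connectivity
analysis from raw dual-wavelength intensities to a Bayesian multilevel
model of channel-wise connectivity degree, together with a synthetic-data
generator that makes every stage testable against known ground truth.
This note records the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic validation does and does not
establish about real data.

## Signal model and synthetic data

A continuous-wave acquisition is emulated: 44 long source–detector
channels (mean separation 3.5 cm) and 8 short channels (0.76 cm) at two
wavelengths (760/850 nm), sampled at 5.1 Hz. Recordings default to
300 s; durations of the kind of resting-state session emulated here are
typically 5–10 minutes, and 300 s keeps simulations fast while leaving
11 analysis epochs.

**Latent connectivity.** Ground truth is a binary graph with per-edge
coupling strengths in (0, 1]. Channel HbO series are produced by
Cholesky-mixing independent band-limited (0.01–0.2 Hz) Gaussian sources
toward the target correlation matrix `I + coupling`; when a requested
pattern is not jointly realizable (correlation matrices must be positive
semi-definite) the spectrum is clipped and the diagonal renormalized,
which shrinks correlations toward feasibility but preserves their
ordering. Two graph families are provided: Erdős–Rényi graphs
(`simulate_latent_network`) for property tests, and disjoint-clique
community graphs (`simulate_cluster_network`) whose block structure is
exactly realizable at high coupling — the only way many pairs can
simultaneously correlate above the 0.5 binarization threshold, and hence
the generator used for realistic high-degree cohorts.

**Hemodynamics.** HbR is a −0.4-scaled (optionally lagged) copy of the
neural HbO plus independent noise. Cardiac (1–1.5 Hz), respiratory
(0.2–0.5 Hz) and Mayer-wave (~0.1 Hz) oscillations are superimposed
with per-channel jittered frequency and phase-diffusing modulation
(random-walk phase, 0.08 rad/sample SD) so that independent oscillators
decorrelate within a recording. Physiological oscillations enter HbO
and HbR with a *positive* ratio (+0.3): they are blood-volume effects,
unlike the anti-correlated neural component. This matters: routing
cardiac through the −0.4 neural ratio nearly cancels it at 760 nm
(whose HbR extinction dominates), which would make the scalp-coupling
index meaningless.

**Optics.** Intensities are `baseline · 10^(−ΔOD)` with ΔOD from the
modified Beer–Lambert forward transform (molar extinction coefficients
from the standard hemoglobin compilation shipped as packaged data; the
product separation × partial pathlength factor, default 6.0 at both
wavelengths, is treated as the total effective path). Long channels mix
in a regional superficial process at weight 0.3; short channels carry
that process (plus small noise) as their entire signal. Each regional
superficial process has its own cardiac/respiratory oscillations —
scalp tissue pulses strongly — which is what gives short channels a
valid scalp-coupling index and realistic regression power. Motion
artifacts arrive as global events (default 1/min): half 1-s half-sine
spikes, half baseline shifts, with per-channel amplitude 5–20× the
channel's OD SD but a common sign and gain across wavelengths, because
probe motion is optically coherent. White instrument noise (default
0.3% relative intensity) is added in OD and scaled by source–detector
separation, reflecting the much higher light levels of short channels;
this noise is also what puts the motion-repair step into its intended
operating regime (see below).

## Preprocessing chain

Fixed order, enforced by stage tags (each operation accepts input from
any earlier stage, so stages are individually testable, but refuses
same-or-later stages): intensity → optical density → TDDR motion repair
→ short-channel regression → SCI screening (threshold 0.7, strict
inequality, cardiac band 0.7–1.5 Hz) → spherical-spline interpolation
of bad channels → Beer–Lambert → negative-correlation enhancement →
0.01–0.20 Hz band-pass. No stage changes the sample count.

Numerical choices:

- **TDDR** follows the published robust-regression recipe exactly
  (split at 0.5 Hz, Tukey biweight with tuning constant 4.685 on the
  centred derivative, iterate to weight convergence at 1e-8 or 50
  iterations, re-integrate, restore the fast component); it matches the
  reference implementation to ~1e-8. A caveat worth stating plainly:
  on *noiseless* smooth signals the biweight systematically compresses
  the light-tailed narrowband derivative, altering a pure 0.05 Hz
  sinusoid by ~12% RMS and bounding end-to-end signal correlation near
  0.85. With white instrument noise dominating the sub-0.5 Hz
  derivative — the regime of real continuous-wave recordings and of
  this generator — the repair is close to a benign rescaling
  (correlation with the input > 0.99). The chain runner therefore
  exposes `apply_tddr`; skipping repair on artifact-free data is the
  higher-fidelity choice, and the end-to-end recovery test checks
  > 0.95 correlation without repair and > 0.7 with it.
- **Short-channel regression** pairs each long channel with its
  spatially nearest short channel (midpoint distance) and subtracts the
  least-squares projection onto `[1, short]` per wavelength.
- **Spherical spline**: channel midpoints projected to a least-squares
  sphere; order m = 4 with 7 Legendre terms and 1e-5 regularization,
  interpolating in channel space.
- **Band-pass**: windowed-sinc FIR (Hamming), −6 dB points at the
  stated edges (0.01 and 0.20 Hz) with the stated transition widths
  (0.01 / 0.2 Hz); length from the Hamming rule 3.3·fs/Δf, capped below
  the signal length with a log warning (at 5.1 Hz and 0.01 Hz
  transition the nominal filter outlasts a 300-s recording); applied
  forward–backward for zero phase. The upper transition width equaling
  the upper cutoff is applied literally and flagged in logs.
- **Negative-correlation enhancement**: x′ = (x − (σx/σy)y)/2 with the
  complementary update, which makes corr(HbO′, HbR′) = −1 exactly.

Only long channels are retained after the Beer–Lambert step.

## Connectivity degree

30-s epochs with 5-s overlap (hop 25 s; count ⌊(T−30)/25⌋+1). Epochs
intersecting annotated artifact intervals with positive measure, or
containing any HbO sample with |value| ≥ 10 µM (inclusive; absolute
value of the analysis-ready series), are excluded. The weighted matrix
is the element-wise mean across retained epochs of per-epoch |Pearson r|
between channel HbO series (a `concatenate` aggregate is available);
binarization is inclusive at 0.5, degree is the off-diagonal row sum.
Mean-of-|r| was chosen as the default because epoch-wise computation is
what makes per-epoch exclusion meaningful.

## Degree model

For channel *i*, participant *j*:

    y ~ Poisson(α)
    log α = (b0 + u0_i + w0_j) + (b1 + u1_i)·Group
          + (b2 + u2_i + w1_j)·Session + (b3 + u3_i)·Group×Session

with treatment coding (references Sham, Pre), so Group and Session
contribute two coefficients each and the interaction four; channel
random effects carry slopes for all predictors, participant effects an
intercept and Session slopes. Priors: Normal(0, 2.5) on fixed effects,
Exponential(rate 2, mean 0.5) on the seven block SDs; effects within a
block share one SD and are uncorrelated, matching the model as written.
Degree is modelled as unbounded Poisson even though true degree ≤ 43;
the generator mirrors this by default (a `clip` flag adds the graph
bound for realism experiments).

**Sampler.** A No-U-Turn sampler written for this package: dynamic
trajectories with a slice variable, divergence threshold 1000 on the
joint log-density, dual-averaging step-size adaptation (default target
acceptance 0.95), and a diagonal mass matrix re-estimated over
expanding warm-up windows. Gradients are analytic, evaluated by a
numba kernel. The default parameterization is *mixed*: channel effects
are non-centred, because their SD posteriors can collapse toward zero
(on pipeline-derived degree tables channel identity carries little
signal), which funnels a centred chain; participant effects are
centred, because each participant contributes ~130 observations, making
the effects individually well identified — centring there removes the
fixed-effect/random-mean ridge that slows the non-centred form. Fully
centred and fully non-centred variants remain available; prior-only
sampling (for prior-predictive checks) uses the non-centred form, whose
prior is an exact iid Gaussian.
Defaults are 8 chains × 2,000 iterations (1,000 warm-up). Convergence
is summarized by split-R-hat (≤ 1.01) and bulk ESS (≥ 400 by default)
via ArviZ. An independent affine-invariant ensemble sampler (emcee) run
on the identical log-density is the cross-check in the test suite.

## Decision layer

Average marginal predictions: for each of 1,000 seeded-subsampled
posterior draws, the expected degree of every observed
(participant, channel) unit is computed under each Group×Session cell,
keeping the unit's own random effects, and averaged across units.
Pairwise differences are later-minus-earlier for Session contrasts and
first-listed-minus-second-listed (order DLPFC, VLPFC, Sham) for Group
contrasts — 9 + 9 = 18 comparisons. The 89% HDI is the narrowest
window of ⌈0.89·n⌉ sorted draws (ties to the lowest start). ROPE bounds
are ±0.1 × the response SD (empirical SD of the analyzed degree column
unless overridden); the overlap is the fraction of draws inside the HDI
that also fall inside the ROPE; decisions: rejected < 0.025,
supported > 0.975, otherwise inconclusive, and an HDI straddling both
ROPE bounds is inconclusive regardless.

## Validation scales and what they show

The stochastic validation experiments run at sizes chosen to keep the
full suite within a practical budget, with fixed seeds:

- interaction-coefficient recovery: 16 replicates of the 15-per-group ×
  44-channel design, reduced sampling (2 chains × 200 retained draws);
  ≥ 85% of 89% credible intervals must cover the generating value;
- null error control: 12 replicates of a 5/5/5 × 12-channel cohort under
  the exchangeable null (intercept only, all random-effect SDs zero, so
  every contrast is exactly zero); ≤ 10% of the 216 decisions may be
  "rejected";
- follow-up-only effect: 10 replicates; the treated-vs-sham contrast
  must be rejected at follow-up and unrejected at baseline in ≥ 9;
- simulation-based calibration: 120 replicates of a 2/2/2 × 2-channel
  design with parameters drawn from the model's own priors; the rank of
  the true interaction among thinned posterior draws must pass a
  chi-square uniformity test at p > 0.01.

Passing these shows the estimator, sampler and decision rules are
internally calibrated under the generator's assumptions. The generator
does not emulate several features of real recordings — anatomical
optode geometry and partial-volume heterogeneity, non-stationary
physiology, slow drifts, systemic arterial-pressure coupling between
scalp and cortex, or channel-specific optode-coupling loss — so green
tests certify the pipeline's correctness and calibration, not its
field performance on real heads.

## Known limitations

- The literal TDDR distorts clean narrowband signal (documented above);
  results are faithful to the published algorithm, not an improvement
  on it.
- Eigenvalue clipping in the hemodynamic mixer means requested edge
  couplings on dense non-clique graphs are realized only up to a
  feasibility shrink.
- The NUTS implementation uses a diagonal mass matrix; strongly
  correlated posteriors (small groups, weak identification) mix slowly
  and may need more iterations than the reduced test settings.
- Degree counts above the graph bound are possible under the unbounded
  Poisson model; this mirrors the model's own assumption rather than
  the data-generating physics.
- Because average marginal predictions keep the observed units' random
  effects, small-sample group contrasts reflect chance participant
  imbalance: with 5 participants per group and a participant-intercept
  SD of 0.1 on the log scale, the realized between-group difference has
  an SD near one degree — often outside a ROPE of ±0.5 — so "rejected"
  decisions at small n can track who was sampled rather than a
  population effect. Error control in the strict sense holds for the
  exchangeable null; interpreters of small cohorts should read group
  contrasts with this in mind.
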