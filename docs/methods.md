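# Methods

This note documents the models, estimators and design choices behind
`scenecomplex`, in the spirit of a statistical software appendix: what
is computed, under which assumptions, with which defaults, and what the
synthetic-data tests do and do not establish.

## Scene statistics

**Contrast operator.** Local contrast is the gradient magnitude of
Gaussian first-derivative responses, `sqrt(gx² + gy²)`, at scale
σ = 1.5 px by default (`SceneStatsConfig.scales`; with several scales
the per-pixel maximum is pooled).  This is the simplest linear operator
with the two properties the statistics require: linearity in luminance
(so CE scales with global contrast) and edge selectivity.  The filter
family itself is not the contract — the proxy-validity requirement
below is.  A border of `ceil(3σ)` pixels is excluded from all pooled
statistics because it is contaminated by the filter support; images are
processed at native resolution and must be at least 32×32 and 4σ on a
side.  Colour is collapsed with fixed Rec. 601 weights
(0.299, 0.587, 0.114).

**Summary statistics.** Contrast energy is the spatial mean of contrast
magnitude over the non-border region.  Spatial coherence is the
divisively normalised pooling `mean / (sd + ε)` with ε = 1e-12 — an
inverse coefficient of variation.  CE is therefore linear in global
contrast while SC is invariant to it; a constant non-zero contrast map
hits the `c/ε` ceiling and is reported as maximally coherent, and an
all-zero map has undefined SC (rejected).  For an exactly
Weibull-distributed sample the coefficient of variation is a monotone
function of the shape parameter alone, which is why SC tracks the
Weibull shape γ and CE the scale β.

**Weibull fit.** A 2-parameter Weibull is fitted by maximum likelihood
(`scipy.stats.weibull_min` with the location pinned at 0) to the
strictly positive contrast magnitudes; zeros are discarded and counted.
A location parameter is deliberately not estimated: on discretised
images it is weakly identified and destabilises the MLE.  At least 100
positive samples are required.

**Proxy validity is the contract.** Across a dead-leaves texture
battery spanning 1–500 fragments, Spearman ρ(CE, β̂) and ρ(SC, γ̂) both
exceed 0.8 (the acceptance suite measures ≈ 0.9 for both).  Any
alternative contrast operator that preserves these correlations is an
acceptable substitute.

## Complexity binning and matched sampling

The bank is reduced to one complexity score per image: the mean of the
rank-percentiles of CE and SC (equal weights, ties broken by stable
input order).  LOW is strictly below the 25th percentile of the score,
HIGH strictly above the 75th, MED the closed central 35% band
[32.5, 67.5]; because 25 + 35 + 25 < 100, the images in the two gaps
stay unassigned.  Percentiles are linear-interpolation empirical
percentiles over the full bank.

Matching selects, per condition, `n_per_category` animal and non-animal
images: greedy nearest-neighbour pairing in standardized (ce, sc)
space, followed by seeded stochastic single-image swaps accepted when
they reduce a cost combining the standardized mean difference and the
dispersion difference of the two selections.  Swapping stops when the
per-condition equal-variance two-sample *t* and Wilcoxon rank-sum
diagnostics meet the criteria (defaults |t| ≤ 0.2 and p ≥ 0.5 for both
statistics and both dimensions) or after `max_iter` = 10,000 attempts,
in which case an error carrying the best report is raised.  With 160
images per condition the diagnostics have df = 158; a 75% GO-style
subset has df = 118.

## Drift-diffusion model

**Likelihood.** The Wiener first-passage density at the lower boundary
is evaluated through the standardised density f(t/a²; w) with two
series expansions — the image-charge (small-time) sum and the sine
(large-time) series — choosing per evaluation whichever needs fewer
terms for the requested absolute truncation error (default 1e-6, terms
capped at 64).  The upper-boundary density is obtained by the
reflection v → −v, w → 1 − w.  The diffusion coefficient is fixed at
s = 1 and the starting point at z_rel = 0.5 in all fits.  Inter-trial
variabilities (η, s_z, s_t) default to 0; a quadrature wrapper
(Gauss–Hermite over drift, Gauss–Legendre over start) provides the
marginal density when they are enabled.  Decision time is clamped at
rt − t_er ≥ 1e-4 s.

**Simulator.** Euler–Maruyama with dt ≤ 1e-3 s, plus a Brownian-bridge
within-step crossing correction (the probability that the bridge
between consecutive states touched a boundary) and a midpoint
convention for the crossing time.  Together these remove the
leading-order discretisation biases: at dt = 1e-3 the simulated choice
fraction agrees with the analytic absorption probability within Monte
Carlo error at n = 10⁶, and simulated decision-time distributions pass
Kolmogorov–Smirnov tests against the integrated density at n = 10⁵
(dt = 1e-4 is used for the fastest dynamics, where time granularity
itself becomes detectable).  Paths exceeding a 10 s cap are censored,
excluded and counted.

**Response coding.** The upper boundary is the "target" response.  A
target-present (animal) stimulus drifts at +v of its condition, a
target-absent stimulus at −v; with z_rel = 0.5 this is equivalent to
accuracy coding.  In the regression model the trial covariate
modulates the drift magnitude before the stimulus sign is applied,
`v_i = v_cond + w_cond · x_i`, with the covariate z-scored within
subject (so weights are comparable across subjects; an unstandardised
option exists).

**Hierarchical estimation.** Subject-level parameters — v per drift
cell, log a per boundary cell, t_er, and optionally w per drift cell —
are drawn around group means with group spreads.  Sampling is
Metropolis-within-Gibbs: per-parameter-block random-walk Metropolis on
subject parameters (step sizes adapted toward 44% acceptance during
burn-in only), conjugate normal / inverse-gamma Gibbs updates for group
means and variances.  Priors are weakly informative: group drift means
N(0, 2²); group log-boundary means N(log 1.5, 0.5²); group t_er mean
normal around 0.3 s with subject t_er bounded to [0.01, 1.0] s (a hard
uniform window would behave equivalently here; the normal keeps the
Gibbs step conjugate); variance priors InvGamma(2, 0.02).  Chains are
initialised from per-subject EZ-diffusion closed forms with
chain-specific jitter.  Desk-scale defaults are 3 chains × 2,000 draws
after 500 burn-in; the full-scale settings (3 × 20,000, burn 5,000 for
the behavioral model; 4 × 20,000, burn 7,500, thin 10 for the
regression model) are available through `MCMCConfig`.  Convergence is
monitored with the split-chain Gelman–Rubin statistic per group
parameter; any R̂ > 1.1 flags the trace as non-converged (it is
returned, flagged, not discarded).  The boundary reported per cell is
the lognormal mean `exp(μ + σ²/2)` of the subject distribution.

**Hypothesis tests on posteriors.** Against zero: the fraction of
draws on the non-dominant side of zero.  Between parameters: the
fraction of draws of distribution 1 beyond the mean of distribution 2,
on the side opposite its own mean.

**Model factors.** Drift varies over the three complexity conditions.
The boundary may vary over condition × instruction (the general
contract) but the canonical fits, like the study design they mirror,
use instruction only — the generating model has no condition effect on
the boundary, and the leaner parameterisation roughly halves the
sampling cost.  The regression model pools both instructions and lets
the boundary vary by instruction.

**EZ diffusion** provides closed-form (v, a, t_er) from accuracy, RT
mean and RT variance of correct trials in a single cell.  It is used
as an independent oracle for the sampler and for chain initialisation,
never as the primary estimator; accuracies of exactly 0.5 or 1 are
rejected rather than edge-corrected.

## Behavioral and ERP statistics

**RT filtering.** RTs below 150 ms are removed as fast guesses; then,
per subject, RTs above mean + 3 sd of that subject's remaining RTs.
On the synthetic studies this removes ≈ 2% of trials (the slow tail of
the diffusion process), and subjects left with fewer than 10 trials
are flagged.

**Repeated-measures ANOVA.** Classical balanced within-subject
decomposition (one or two factors), each effect tested against its own
subject-by-effect interaction; partial η² = SS_eff/(SS_eff + SS_err).
A perfectly null effect (both sums of squares zero) reports F = 0
rather than 0/0.  The implementation is cross-checked against
statsmodels' AnovaRM in the test suite and against the F = t² identity
for two-level factors.  Post-hoc pairwise paired t-tests use the Šidák
adjustment 1 − (1 − p)^m.

**ERP chain.** Epochs (trials × channels × time, −100 to 500 ms at
256 Hz in the synthetic default) are pooled over the 8-channel
occipital set Oz, POz, O1, O2, PO3, PO4, PO7, PO8 (configurable; a
9-channel variant including PO6 exists in the literature and can be
passed instead).  Difference waves are subject-level mean(animal) −
mean(non-animal) per condition and instruction; the grand average
carries the between-subject SEM.  Point-wise two-tailed tests are
one-sample t against zero per condition and paired t for HIGH−LOW,
HIGH−MED, MED−LOW.  All instructions × contrasts × timepoints are
concatenated into a single Benjamini–Hochberg family at α = 0.01
(per-contrast families are available behind a flag), and the empirical
q threshold — the largest passing p — is reported.  ERP averages
include all trials by default with a correct-only option.

**Divergence onset** is the earliest post-stimulus timepoint starting a
run of at least 5 consecutive significant samples (~20 ms at 256 Hz).
The run criterion exists because isolated single-sample exceedances are
expected from any point-wise procedure and are not interpreted as
effects; onset statements in the tests use the same run-based rule.

**Window amplitude** is the per-trial mean of the pooled signal over
220–325 ms, endpoints inclusive — the interval from the onset of the
high-complexity difference wave to its peak — and is the trial-level
regressor fed to the drift regression.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume,
not the physics that produces it.

* **Images**: dead-leaves compositions of k random ellipses over a flat
  background (optional white or 1/f noise; the default is noise-free so
  flat regions carry exactly zero contrast).  Fragment count k drives
  CE and SC monotonically (ρ ≈ 0.95 with CE, ≈ 0.93 with SC across
  k = 1…500).  Banks draw k log-uniformly and assign animal/non-animal
  labels independently of k, so both categories populate every
  complexity level and matching is feasible.
* **Behavior**: subject parameters drawn normally around group truth
  (defaults: v = 1.4/1.3/0.8 for LOW/MED/HIGH, a = 1.0/1.8 for
  speed/accurate, t_er = 0.3 s; between-subject sds 0.15/0.10/0.03),
  trials simulated per balanced condition × instruction × category
  cell.  The default study is 20 subjects with 160 trials per
  condition under each instruction — the layout of a design that shows
  every image twice, once per instruction.
* **EEG**: each trial is a condition baseline (P1/N1-like components)
  plus, for animal trials of the configured conditions (default HIGH
  only), an effect template rising as a half-Gaussian from 220 ms to
  full amplitude (2 μV) at 325 ms and sustained thereafter, scaled by
  a trial gain (sd 0.3); trial noise (sd 4.5 μV shared across
  channels) and independent channel noise (sd 3 μV) are added.  These
  noise levels give comfortably suprathreshold point-wise power at the
  default study size while keeping single-trial amplitudes noisy, as
  real window amplitudes are.
* **Joint coherence**: the trial's *measured* 220–325 ms window
  amplitude — exactly what the analysis later recomputes from the
  saved epochs — is z-scored within subject and inserted into that
  trial's drift (`v_i = v_cond + w_cond·z_i`, floored at 0.05) before
  the RT is simulated, with default weights w = −0.03/−0.03/−0.10.
  Recovery of w by the regression model therefore tests the entire
  inferential chain, not a shortcut.

What passing tests show — and what they do not.  The recovery tests
establish that the estimators are consistent with their own generating
model at realistic sizes.  Real EEG has spatially and temporally
correlated noise, artifacts, subject-varying effect latencies and
topographies, and real RT data contain contaminants beyond the
diffusion process; none of these are emulated, so the tests validate
the machinery, not its robustness to violations.

## Numerical and design notes

* The absorption probability uses the standard closed form
  P(upper) = expm1(−2vaw/s²)/expm1(−2va/s²) with the v → 0 limit
  z_rel, verified against both the integrated density and large-scale
  simulation.
* Seeds are explicit everywhere; identical seeds give byte-identical
  banks, trials, epochs and traces.  Sub-seeds are derived
  deterministically and kept below 2³¹.
* The pipeline's config hash covers analysis parameters (not paths)
  and is stamped into every output; reruns with the same configuration
  and inputs are byte-identical.
* Stage sizes in the acceptance script (1000-image bank, 20 × 960
  trials, 3 × 2000 draws, 20 onset replications) were chosen as the
  smallest sizes at which the recovery probabilities are stable; all
  scale up through configuration.

## Known limitations

* The Metropolis-within-Gibbs sampler is tuned for the factorial
  models implemented here; it does not expose arbitrary design
  matrices or estimate z_rel, and inter-trial variabilities, while
  supported in the density and simulator, are not sampled
  hierarchically.
* SC's ε-regularisation makes the degenerate constant-contrast case
  finite but enormous; downstream consumers should treat such images
  as pathological.
* The matching algorithm optimises first and second moments; exotic
  distribution shapes could pass the t test yet fail a
  Kolmogorov–Smirnov comparison (the rank-sum diagnostic catches most
  practical cases).
* `divergence_onset` reports the first detected run, which lags the
  true effect onset when the effect ramps up gradually (detection at
  ≈ 270 ms for a 220 ms half-Gaussian onset in the defaults); it is a
  conservative bound, never earlier than the true onset.
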