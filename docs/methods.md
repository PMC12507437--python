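# Methods

## Scope and data model

`vistune` characterizes visual receptive fields of single units recorded while
drifting sinusoidal gratings are presented.  The raw datum is one trial: a
stimulus condition (direction, spatial frequency SF, temporal frequency TF,
contrast, 4 s duration) or a gray-screen blank of matched duration, and the
unit's mean firing rate over the stimulus window.  Two condition batteries are
supported, mirroring a common experimental design:

* **B1** — 4 orientations × 8 SFs (0.04–1.25 cpd) × 6 contrasts (0.04–1) at
  4 Hz, gratings drifting back and forth (orientation stimuli), 5 repeats,
  plus one blank;
* **B2** — 8 directions × 7 TFs (0.5–32 Hz) at 0.1 cpd and full contrast,
  unidirectional drift, 7 repeats, plus one blank.

Battery membership (including each battery's blank) is encoded in the trial
table's `drift_mode` column; back-and-forth conditions are orientation stimuli
(direction modulo 180° is the informative quantity).

## Response extraction

Responses are blank-subtracted condition means (Hz, signed: suppression below
background is preserved).  An F1 path is provided for simultaneously recorded
spike times: the complex coefficient (2/T)·Σⱼ exp(−i2πf tⱼ) is averaged across
trials before taking the modulus, so a rate r(t) = m + a·sin(2πft) yields
F1 = a.  Coherent (vector) averaging is used deliberately: averaging per-trial
moduli is biased upward by spike-count noise (≈ +1 Hz at typical rates),
whereas the stimulus-locked phase lets the noise cancel.  TF analysis always
uses mean responses because profound suppression makes F1 misleading there.

A unit enters a battery's analyses only if a one-way fixed-effects ANOVA over
all of that battery's conditions (blank included) rejects a common mean at
p < 0.05.  No correction across units is applied; the test is a per-cell
responsiveness gate, and its type-I error is verified to be nominal under a
Poisson null.

Tuning curves are sliced at empirically preferred fixed parameters: preferred
orientation is the argmax over orientations of full-contrast responses averaged
over SF; preferred SF the argmax at that orientation at full contrast;
preferred direction the argmax over directions of the TF-averaged responses;
preferred TF the argmax at that direction.  Ties break toward the lower angle
or frequency, making the slicing deterministic.

## Selectivity

Orientation selectivity is 1 − CV = |Σ rₖ e^{i2θₖ} / Σ rₖ| (angles doubled);
direction selectivity is the analogous resultant without doubling.  Negative
blank-subtracted responses are clipped to 0 before the resultant, since the
resultant is only interpretable with nonnegative weights; `rectify=False`
exposes the raw-signed alternative.  Angle preference comes from a double
Gaussian R(θ) = B + A₁G(θ−θp) + A₂G(θ−θp−180°) with a shared width, lobes fixed
180° apart, wrapped angular differences, deterministic multi-start (θp at each
sampled angle × widths {15°, 30°, 60°}, amplitudes solved linearly) and bounded
refinement; a fit is accepted when it explains ≥ 50% of variance.

## Frequency tuning

SF and TF curves are fit with R(f) = k·exp(−(f/fc)²) / (1 + (fh/f)^β):
a Gaussian high-frequency falloff with corner `fc` and a low-frequency
attenuation with corner `fh` and steepness `β` (fh = 0 gives a pure low-pass
curve).  Fitting is bounded least squares (k ≥ 0, fc and fh within an
octave-padded tested range, β ∈ [0.5, 8]) with a deterministic coarse grid over
(fc, fh, β), the gain solved in closed form per grid point, the best starts
refined with an analytic Jacobian.  Two response transforms are supported:
`rectified` (negatives clipped) and `absolute` (suppression counted as
response), giving the two bandwidth variants.

Half-height cutoffs follow the fitted continuous curve from its peak (located
within the tested range): L50 and H50 are the first frequencies where the
response drops to half its maximum.  If the response never drops to half-max
at or above the lowest tested frequency the cell is low-pass (L50 = 0);
likewise high-pass gives H50 = ∞.  Bandwidth is log₂(H50/L50) octaves,
infinite for low- and/or high-pass cells.  The low-pass index
LPI = R(f_lowest)/max_f R(f) and its high-frequency twin HPI are computed from
*measured* rectified responses, not the fit, because the definition enumerates
the tested frequencies.

## Contrast and excitability

Contrast curves are fit with the Naka–Rushton function
R(c) = R_max·cⁿ/(c₅₀ⁿ + cⁿ) + B (bounded multi-start least squares; c₅₀ ≤ 1.5,
n ∈ [0.5, 6]).  Contrast sensitivity is 1/c*, where c* is the lowest contrast
at which the fitted response rises 5 blank-trial standard deviations above
baseline, solved in closed form; the crossing contrast is floored at 1e−6 so a
zero threshold yields a finite answer, and sensitivity is undefined when the
curve never crosses at c ≤ 1.  Excitability is summarized per unit by the peak
blank-subtracted response (floored at 0), the deepest suppression below
background (0 if none), and the background rate (mean blank rate pooled over
batteries; subtraction itself uses each battery's own blank).

## Group inference

Per-cell metrics are compared across the four rearing groups (control,
EO1contra, EO1ipsi, EO2) with a linear mixed-effects model: group fixed
effects with control as the reference level and a random intercept per animal,
REML estimation, Wald tests on the coefficients (statsmodels `MixedLM`).
Degenerate inputs (zero within-group variance) fall back to exact group means
with a flag.  Group medians are reported alongside model means.  Metrics with
infinities (octave bandwidths) are first rank-transformed: finite values get
average ranks ascending and every infinite value shares the top average rank.
Angle-preference distributions are compared with a chi-square homogeneity test
on 45° bins (360° space for direction, 180° for orientation); bins empty in
all groups are dropped.  No multiple-testing correction is applied across
metrics.

## Synthetic data generator

The generator exists so every stage can be exercised at desk scale with known
ground truth.  Each simulated neuron composes the same parametric families the
analysis fits, each profile normalized to 1 at its peak:

    rate = background + k·dir(θ)·tf(f)·sf(s)·contrast(c)
           − suppression_depth·min(1, (f/32)²),  clipped at 0.

Direction tuning is the wrapped double Gaussian (anti-preferred amplitude =
`dir_selectivity` × preferred; back-and-forth stimuli pool the two drift
phases).  TF and SF profiles use the frequency model above; the contrast
profile is a baseline-free Naka–Rushton.  The suppression term is a negative
lobe deepening toward the highest tested TF, reproducing below-background
responses phenomenologically.  Trial spike counts are Poisson over the 4 s
window (an assumption — trial-to-trial variability of the real units is not
characterized; a `dispersion` knob switches to gamma-mixed Poisson).  Animal
random intercepts act additively on background, multiplicatively (lognormal)
on the gain, and additively on the target low-pass index, keeping rates
nonnegative.

Two generator parameterizations deserve comment:

* **Low-pass index as a target.**  A unit's `fh` is solved by bisection so its
  noise-free LPI over the tested TF grid equals a drawn target; group LPI
  means are therefore configured directly (defaults 0.20 control, 0.35
  EO1contra, 0.22 EO1ipsi, 0.33 EO2, matching the reported population values,
  alongside background rates 2.6/6.6/11.1/6.6 Hz and group-specific
  suppression depths).
* **SF broadness.**  The SF falloff is deliberately shallow (fc = 8·sf_peak,
  with fh chosen so the peak sits exactly at `sf_peak`).  Narrow SF profiles
  would make units with preferred SF ~0.03–0.05 cpd unresponsive to the fixed
  0.1 cpd battery-2 grating, contradicting the observed physiology this
  generator emulates (robust direction/TF tuning measured at 0.1 cpd;
  predominantly low-pass SF tuning).

What passing recovery tests show — and what they do not: the generative and
fitted families coincide, so parameter recovery demonstrates correctness of
the estimation chain, not robustness to model misspecification.  Real data
add overdispersion, adaptation, eye movements and spike-sorting noise that the
generator does not emulate.

## Problem sizes and numerics

Simulation-based checks use sizes chosen to make Monte-Carlo error small
relative to the tested tolerances: 1000 Poisson-null units for the inclusion
ANOVA calibration; 20 seeded replicates of a 4-group × 6-animal × 20-unit
simulation for end-to-end group-mean recovery; 500 null and 200 effect
replicates for mixed-model calibration; the acceptance script reports group
statistics from a 6-animal × 12-unit-per-animal run of both batteries.  All
simulations are seeded and every fit is a deterministic function of its input
curve (fixed multi-start grids, no stochastic restarts).  Optimizer
tolerances: least-squares xtol/ftol ≈ 1e−11 with analytic Jacobians for the
frequency model; cutoff root-finding by bisection to 1e−12.

## Known limitations

* The F1 pathway is exercised by unit tests but the generator emits rates
  only, so modality choice defaults to mean responses in simulated pipelines.
* Contrast fits carry no group-level benchmark; they are validated by
  self-consistency and closed-form identities only.
* With few animals per group, Wald tests on mixed-model coefficients are
  mildly anti-conservative; the type-I error is verified to stay below 9% at
  α = 0.05 for the study's design, but small-sample corrections (Satterthwaite
  or Kenward–Roger) are not implemented.
* Importing the archived experimental dataset's native format is out of scope;
  the CSV trial table is the ingestion boundary.
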