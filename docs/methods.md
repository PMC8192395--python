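# Methods

This note documents the models, numerical choices, and defaults behind
`trainability`, and what the synthetic-data generator does and does not
emulate.

## Responder classification (ROPE + HDI)

Each participant's ∆V̇O₂max (POST − PRE, mL·min⁻¹) is given a normal
uncertainty distribution derived from the technical error of the V̇O₂max
measurement. With coefficient of variation `cv` (default 0.056):
measurement error = PRE·cv/2; the individual range is ∆ ± error; and
∆sd = (range width)/4 = PRE·cv/4, on the reading that ~99.9 % of a normal
lies within ±2 SD of the mean, i.e. 4 SDs span the range. The alternative
reading (half-width/4, giving PRE·cv/8) is available as
`range_convention="half_width"`.

The 89 % HDI of Normal(∆, ∆sd) is computed analytically — for a normal the
HDI is the central interval ∆ ± z·∆sd with z = Φ⁻¹(0.945) ≈ 1.5982.
A sampling construction (narrowest window over n = 100 simulated measures)
is retained behind `hdi_method="simulated"` for fidelity, but is not the
default: at n = 100 the HDI endpoints have enough sampling noise to flip
borderline labels, which makes the decision rule non-deterministic for no
analytical benefit.

The ROPE is ±20 % of the cohort baseline SD (the "smallest worthwhile
difference"), or an explicit interval; the explicit ±80 mL·min⁻¹ is the
default because the published analysis used that rounded interval (the
group SDs imply ~±72–85 depending on pooling, which is not stated).
`pct_hdi_in_rope` is measured on interval *length*; a probability-mass
variant (`overlap="mass"`) is provided since conventions differ across
implementations. Labels: 0 % in ROPE → responder; 100 % → non-responder;
otherwise undecided; negative ∆ always forces non-responder. The label is
monotone in ∆ at fixed baseline.

Numerics: the percentage is computed as `100·(overlap/width)` — ratio
first — so that a fully contained HDI yields exactly 100 and the
non-responder branch is taken deterministically; a zero-width HDI (cv = 0)
scores 100 if ∆ lies in the ROPE and 0 otherwise.

## CPET processing

Breath editing removes V̇O₂ records deviating from the centred rolling
mean (window 11 breaths) by more than z = 1.96 rolling SDs, one pass; edge
breaths without a full window are kept. The window statistics *include*
the evaluated breath: this caps the attainable deviation/SD ratio near 3
but also self-protects clean breaths, giving a ~2–3 % false-removal rate
on Gaussian noise (the unavoidable floor of a 95 % band) while still
catching ≥ 90 % of gross artefacts (10+ local SDs) at a 2 % artefact rate.
Two same-sign artefacts inside one window can mask one another (ratio
≈ 2.0); recovery statements are therefore made in aggregate over seeds.

The edited series is linearly interpolated to a 1 Hz grid from first to
last breath and averaged into non-overlapping 30-s bins anchored at the
first sample; a trailing partial bin is kept only with ≥ 15 s of data.
V̇O₂max is the highest bin mean; PO_peak the last recorded power (power at
task failure, not interpolated within a stage); HRmax the maximum over the
test; RER the maximum binned V̇CO₂/V̇O₂. Attainment is two-of-three:
|HRmax − (220 − age)| ≤ 10 bpm, RER > 1.10, peak lactate ≥ 8 mmol·L⁻¹;
with no lactate sample the rule is evaluated on the remaining two.

## Lactate thresholds and efficiency slopes

Stage summaries take, per completed 3-min stage (constant positive power
segment, tolerance 8 s for irregular breath timing): last-30 s HR mean,
last-60 s V̇O₂ mean (the steady portion of the stage; the window is a
package choice), and the end-stage lactate sample matched by power.

LTP1/LTP2 come from a continuous three-segment piecewise-linear least
squares fit of lactate on power, in the hinge parameterisation
`c₀ + c₁p + c₂(p−b₁)⁺ + c₃(p−b₂)⁺` (continuity at both breakpoints holds
by construction — the standard segmented-regression constraint). The
breakpoint pair is found by exhaustive search on a 1-W grid spanning the
observed power range, with at least one stage in each outer segment; for
each candidate pair the linear coefficients are solved in closed form
(batched normal equations with a pseudoinverse), and the global SSE
minimiser is returned with ties broken toward the smaller b₁ then b₂.
Grid search is deterministic and globally optimal at stage-test sizes
(~10 points, ~2·10⁴ candidate pairs, milliseconds); iterative breakpoint
estimators can converge to local optima here. On noiseless three-segment
data with ≥ 2 stages per segment the recovery is exact. Fewer than four
lactate stages or constant lactate raise errors. The resting lactate
sample can optionally enter the fit as a pseudo-stage at 0 W.

Threshold V̇O₂ (and HR) values are OLS lines of stage V̇O₂ (HR) on stage
power evaluated at the breakpoints. OUES is the OLS slope of V̇O₂
(mL·min⁻¹) on log₁₀V̇E over exercise-phase 30-s bins; rescaling V̇E changes
only the intercept. ∆V̇O₂/∆PO and ∆HR/∆V̇O₂ are plain OLS slopes on the
exercise phase (resting data excluded).

## NIRS reperfusion metrics

Baseline StO₂ = mean over the 120 s before cuff inflation. Reperfusion
slope (slope 2) = OLS slope over [release, release + 10 s) — the release
sample included, window half-open — where the signal is linear. AUC =
trapezoidal integral of max(StO₂ − baseline, 0) over [release,
release + 240 s], endpoint included for quadrature accuracy; clipping
negative deviations prevents sub-baseline dips cancelling hyperaemic
overshoot (an unclipped signed integral is available, since the original
convention is not stated).

## Training prescription, monitoring, load

HIIT: 10-min warm-up at the power of 70 % HRmax, 4 × 4-min intervals at
the power of 90 % HRmax, 4-min recoveries and 5-min cool-down at 30 W
(2580 s total). Powers invert the OLS HR–power line fitted to last-30-s
stage heart rates; watts are rounded to integers (ergometer resolution).
MICT: 3600 s at round(0.9·LTP1 power); target HR is the HR–power line at
that power.

Weekly monitoring: each session's HR is cleaned against a centred rolling
median (window 31 s) with a 3·(1.4826·MAD) band — a robust band, since the
anomaly-detection tool used originally is cited without parameters —
deleted points re-interpolated at 1 Hz; the week's sessions are aligned on
elapsed time, ensemble-averaged, and binned to 5 s. The observed HR (mean
of the four intervals' last-120-s means for HIIT — the all-intervals
reading of the adjustment rule; the whole-session mean for MICT) is
compared with the prescribed HR ± 3 bpm: below the band, +5 W next week
(intervals / continuous power); above it, an ergometer-recalibration flag.
The rule is one-sided: prescribed power never decreases.

Session metrics: total work Σ P·∆t (kJ), kcal = work/4.184, relative
values per kg body mass, %PO_peak, %HRmax, %HR-reserve — for HIIT both
whole-session and intervals-only. iTRIMP sums, over 5-s bins,
∆t[min]·x·a·e^{bx} with x the HR-reserve fraction clipped to [0, 1] and
(a, b) from a nonlinear least-squares fit of stage lactate on stage x
(log-linear start values); if unfittable, generic constants (0.64, 1.92)
are used with a warning flag.

## Bayesian predictor regression

On the standardized scale (z-scored predictors and response — the
interpretable reading of "scaled by the mean and SD of the response";
the literal mode that centres/scales everything by the response's moments
is kept as `standardize_mode="response"`), the model is y = α + Xβ + ε,
ε ~ N(0, σ²), β|σ² ~ N(0, σ²·2.5²I) (intercept scale 10), σ² ~
Inv-Gamma(2, 1) — a normal–inverse-gamma family chosen so the posterior is
available in closed form. Two backends target the same posterior:
blocked Gibbs MCMC (4 chains × 2000 iterations, warm-up 1000, seeded via
`SeedSequence.spawn`) reporting split-chain R̂ per coefficient, and the
analytic conjugate posterior with i.i.d. draws whose exact mean serves as
a deterministic oracle. Agreement of the two backends within Monte-Carlo
error is part of the test suite.

Summaries per coefficient: posterior median, 89 % HDI (narrowest window
over sorted draws), share of draws in the ±0.01 standardized ROPE, a
significance call when the HDI excludes the ROPE, and a Funder-style
magnitude label (|β| < 0.05 tiny; < 0.1 very small; < 0.2 small; < 0.3
medium; < 0.4 large; else very large). One model is fitted per
predictor-domain panel rather than one grand model — with n = 21 per
group, a joint model over all domains would be badly underdetermined.

## Group statistics

Welch's t (via `scipy.stats.ttest_ind_from_stats`) with Welch–Satterthwaite
df, and Cohen's d with the root-mean-square-SD denominator
d = (m₁ − m₂)/√((s₁² + s₂²)/2) and normal-quantile CI on
SE = √((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂−2))). These conventions are the pair
that exactly reproduces the published effect size and interval from the
printed summaries; pooled-SD and t-quantile variants are flags.

## The synthetic cohort generator

The generator draws baselines from Normal(group mean, group SD) truncated
at 1000 mL·min⁻¹ and relative changes from Normal(group %, group SD%),
independently by default (their covariance is unreported; a correlation
knob exists). Sex is assigned so that the smaller absolute baselines are
female (absolute V̇O₂max scales with body size, and the test protocol's
starting power is sex-specific); ages, masses, resting/maximal HR and the
HR–power and V̇O₂–power relations are drawn around population-typical
values, with HRmax a little below 220 − age. Lactate follows a noiseless
three-segment piecewise-linear curve with integer-watt breakpoints at
~45 % and ~74 % of peak power (additive Gaussian noise, SD 0.2 mmol·L⁻¹,
floored at 0.5). Breath sampling is irregular (mean 2.5 s, jittered) to
exercise interpolation; breath noise SD 80 mL·min⁻¹; spike artefacts are
10–18 local SDs at a configurable rate. V̇O₂ rises linearly with power and
plateaus at V̇O₂max; the final stage is held ≥ 60 s so the plateau covers a
full 30-s bin, making noiseless V̇O₂max recovery exact. The incremental
test ends where the HR line reaches HRmax. NIRS traces are 2 Hz with a
120-s baseline, 300-s occlusion (exponential desaturation), an exactly
linear 10-s reperfusion at the injected slope, and a hyperaemic overshoot
decaying back to baseline. Training logs are 1 Hz with first-order HR
dynamics (τ = 30 s) toward the HR–power line, plus noise and 25–60 bpm
artefacts; a weekly HR drift knob emulates fitness gain and drives the
+5 W rule. The POST test raises V̇O₂max by the injected ∆ and flattens the
HR–power slope accordingly (training bradycardia at a given workload),
which is what makes the gain measurable in an HR-limited test.

Not emulated: V̇O₂ slow-component and on-kinetics, RER/V̇E dynamics beyond
monotone ramps, day-to-day biological variation beyond the stated noise
terms, dropout/adherence, and any covariance structure among predictors
beyond what the injected effects induce. Passing tests therefore
demonstrate correctness of the *processing and decision chain* under the
stated generative assumptions, not robustness to every artefact of real
breath-by-breath data.

The end-to-end pipeline additionally applies an eligibility screen
(participants are redrawn until the implied test yields ≥ 4 completed
stages), mirroring the screened study population; the plain distribution
is used everywhere distributional claims are tested.

## Problem sizes and tolerances

Closed-form oracle comparisons use 1e-9 (absolute or relative) tolerances.
Simulation checks use: 2000 cohorts × 21 participants for responder
rates; 500 (noise-recovery) or 200 (aggregate) replicates for NIRS slopes;
120 replicates for noisy lactate-threshold recovery (median |error| within
one 25-W stage); 100 seeded replicates for regression sign recovery and
HDI calibration at n = 200; 50 random configurations for exact noiseless
breakpoint recovery. These sizes keep Monte-Carlo error comfortably below
the asserted margins while the full suite runs in well under a minute's
worth of simulation per module.

## Known limitations

* The responder decision inherits the printed ±80 mL·min⁻¹ ROPE rather
  than deriving it from each cohort (derivation is one flag away).
* The exact iTRIMP weighting constants of the original analysis are not
  recoverable; the generic fallback (0.64, 1.92) follows the standard
  exponential lactate-weighting literature.
* Segmented-regression grid search assumes integer-watt breakpoints are
  adequate resolution (ergometer stages are 25 W apart).
* The Gibbs backend's inverse-gamma residual prior is chosen for exact
  conditionals; with n in the tens and standardized data its influence is
  negligible, but it is not a half-Cauchy.
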