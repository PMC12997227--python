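# Methods

`fmtheta` re-creates, on synthetic data with known ground truth, a complete
MEG analysis of task-induced frontal-midline theta (FMΘ) in a Go/NoGo
response-inhibition task: from epoched magnetometer data through induced
time–frequency power, LCMV source projection, cluster-mass permutation
statistics, an ROI mixed model, and behavioral signal-detection analysis.
This note documents the generative model, the analysis chain, the numerical
choices, and what the synthetic world does and does not show about real data.

## The synthetic cohort

Two groups are simulated: 17 "control" subjects and 10 "stroke" subjects,
each performing a Go/NoGo session of 504 trials (25% NoGo, 200 ms stimuli,
1100 ms response window, 2000–2700 ms inter-stimulus intervals, 3 blocks).

**Behavior.** Go correctness is Bernoulli(hit rate), NoGo commission errors
Bernoulli(false-alarm rate); emitted response times are ex-Gaussian
(μ, σ, τ) truncated to the response window. The template rates
(hit ≈ 0.994/0.992, false alarm ≈ 0.042/0.060 for control/stroke) and RT
parameters (μ, σ, τ = 450, 50, 110 ms control; 440, 40, 95 ms stroke) were
calibrated once so that group medians land near d′ ≈ 4.2/3.7 and median
RT ≈ 530/510 ms — plausible near-ceiling Go/NoGo performance in older
adults. A configurable 1% of responses is replaced by anticipatory RTs
(< 100 ms) so rejection rules are exercised.

**Sensor epochs.** The head is a homogeneous conducting sphere (radius
80 mm, centre at the origin of a canonical template-like frame); sensors
are 102 (default; 32 at desk scale) radial magnetometers on a Fibonacci cap
at 102 mm. Each 3 s epoch (−1.5…+1.5 s, endpoints included) contains:

- a **midfrontal theta dipole** at (0, 35, 45) mm, tangentially oriented,
  with source time course
  `amplitude · [tonic + g_cond · w(t)] · sin(2π f t + φ)`, `f` drawn per
  trial in 3.5–5.5 Hz and `φ` uniform — induced, not phase-locked. The
  burst envelope `w(t)` is a raised cosine on 150–650 ms (peak 400 ms), so
  the 250–500 ms analysis window sits inside it;
- a **phase-locked evoked component** (Gaussian-windowed 4 Hz wave,
  identical across trials) through the same dipole;
- an **occipital 10 Hz background dipole** with random phase per trial; and
- white sensor noise (2·10⁻¹³ T SD), inflated 8× in a random 1% of epochs
  to create variance outliers.

Group structure mirrors the qualitative target pattern: controls have
`g_NoGo / g_Go = 2` with tonic gain 1; stroke subjects have tonic gain 0.6
and `g_NoGo = g_Go` (no inhibition-specific modulation). Per-subject
lognormal jitter (SD 0.15 on gains, 0.25 on miss/false-alarm rates) makes
subjects exchangeable draws rather than copies. A ground-truth JSON records
the planted location, orientation, tonic levels, and the expected relative
power change per condition, computed from the taper-weighted envelope
(see below).

## Analysis chain

**Preprocessing** (fixed order): remove incorrect trials, then responded
trials with RT ≤ 100 ms, then a single-pass variance screen (per-epoch
channel-averaged temporal variance > mean + 2 SD over surviving epochs,
sample SD); randomly subsample correct Go trials to the NoGo count; subtract
the per-condition trial-average waveform (ERF) so only induced activity
remains. The subsampled Go set's own mean is used for the subtraction.

**Time–frequency.** Sliding fixed 1 s Hanning window, frequencies 1–15 Hz
in 0.5 Hz steps, time points every 50 ms. Spectra are evaluated by direct
DFT at the requested frequencies, which is identical to zero-padding to 8 s
and picking bins (padding only interpolates; all requested frequencies lie
on the padded grid when `pad_to · f` is an integer). Normalisation is the
one-sided density convention `2|X|²/(sfreq · Σ taper²)`; only relative
change is interpreted downstream, which is normalization-invariant (tested).
Window positions extending past the epoch are flagged missing (NaN) and
excluded from averages — zero-filling would bias relative change. Baseline
correction is fractional change relative to mean power in −1500…−500 ms.

**Source projection.** Sarvas' closed-form field of a current dipole in a
conducting sphere gives, at each point of a regular grid (6 mm default,
15–24 mm at desk scale, points kept strictly inside 0.9× the sphere
radius), a rank-2 leadfield in a deterministic tangential basis
(`ẑ × r̂` and its complement; radial sources are externally silent). The
exact grid centre is itself silent and is excluded from filtering. A
common LCMV filter per subject is built from the covariance pooled over all
Go and NoGo epochs (per-epoch means removed) with diagonal loading
λ·trace(C)/n at λ = 5%. The scalar (orientation-optimised) variant is
used: the tangential direction minimising `u'(L'C⁻¹L)u`, i.e. the smallest
generalized-eigenvalue direction, which maximises output power under the
unit-gain constraint `w'l = 1`. The filter sign (unidentifiable) is fixed
by making the first non-negligible weight positive.

**Cluster statistics.** The control group's per-subject NoGo − Go window
contrasts (3–6 Hz, 250–500 ms average per grid point) enter a one-sided
dependent-samples cluster-mass permutation test: element-wise one-sample t,
cluster-forming threshold at the upper α = 0.05 t-quantile (strict
inequality), connected components under the 6-neighbour grid graph, null
distribution of per-permutation *maximal* cluster masses under random
whole-map sign flips per subject (the exchangeability unit for a paired
contrast), p = (1 + #{null ≥ observed})/(1 + n_perm). An exact mode
enumerates all 2ⁿ sign patterns. The space–time–frequency variant runs the
same machinery on the Cartesian product graph (grid neighbours × ±1
frequency bin × ±1 time bin) restricted to 1–10 Hz and 0–1 s.

**ROI analysis.** The ROI is the largest significant cluster; when no
cluster is significant (possible in small null cohorts) the battery falls
back to the planted source's grid neighbourhood and flags the report. Two
bookkeepings coexist deliberately: State comparisons (baseline −1500…−500
vs active 250…500 ms) use raw, non-baseline-corrected theta power; ΔFMΘ
(per-subject NoGo − Go in the analysis window) uses baseline-corrected
relative change. The factorial model
`Power ~ Group × State × Condition + (1|Subject)` is fitted by REML with
sum-to-zero (±1) coding. With equal cluster sizes the marginal covariance
is `σ²(I + ρZZ')`, whose inverse and determinant are analytic; the REML
criterion is profiled to one dimension in ρ and optimised deterministically.
Type III F tests use the Wald statistic per single-df term with the
residual-df convention `df2 = n_obs − 8` (108 observations at the target
cohort → df2 = 100), and partial eta squared is recovered as
`F·df1/(F·df1 + df2)`. Follow-ups: paired Wilcoxon signed-rank tests
(baseline→active, per group × condition, two-sided), Mann–Whitney rank-sum
tests (control vs stroke, per state × condition, two-sided), and for ΔFMΘ a
one-sided rank-sum test (control > stroke), a two-sided Kolmogorov–Smirnov
test, a within-group bootstrap (10,000 resamples by default: percentile 95%
CIs of the rank-biserial correlation and the median group difference,
direction consistency, p-stability = fraction of resamples with p < 0.05),
and leave-one-out influence analysis (clinical-group members by default).

**Behavioral statistics.** d′ uses the log-linear correction
Ĥ = (H + 0.5)/(N_signal + 1), F̂ = (F + 0.5)/(N_noise + 1),
d′ = Φ⁻¹(Ĥ) − Φ⁻¹(F̂), with an internal normal quantile (rational
approximation plus one Halley refinement; absolute error ≲ 1e-15, verified
at 1e-8 across the full count grid). Group comparisons are one-tailed
Mann–Whitney tests in the direction of poorer inhibitory control after
stroke.

## Statistical conventions

- **Rank-biserial correlation** `r = 2U/(n_x n_y) − 1` where U counts pairs
  favouring the first sample; matched-pairs version for the signed-rank test.
- **z statistics** use tie-corrected variances and a continuity correction
  of 0.5 shifted toward the tested tail (one-sided) or shrinking |U − μ|
  (two-sided). This convention reproduces, e.g., z = 2.03 from U = 126 at
  group sizes 17/10.
- **Exact p paths**: Mann–Whitney by enumeration for pooled n ≤ 12 without
  ties; signed-rank by 2ⁿ sign-flip enumeration on midranks for n ≤ 12
  (valid with tied magnitudes); Spearman by full permutation for n ≤ 7; KS
  exact for n_x·n_y ≤ 10⁴. Larger samples use tie-corrected normal (or t)
  approximations.
- **Cohen's d** from a dependent-contrast peak t is `t/√n`.

## Expected relative change (generative oracle)

For a slowly varying envelope `a(t)` under a Hanning taper `h`, narrow-band
power at the envelope's frequency is proportional to the squared
taper-weighted mean amplitude. The expected relative change in the analysis
window is therefore
`mean_t [(Σ h·a(t+τ) / Σ h / tonic)²] − 1`, evaluated at the 50 ms analysis
time points. This quantity, exported in the ground-truth file, is what the
full pipeline reproduces within a few percent on noise-free single-dipole
data when the source frequency sits on an analysis bin; with the default
per-trial frequency spread, off-bin leakage dilutes the band-averaged value
slightly (tested at the on-bin frequency with 5% tolerance).

## Problem sizes and defaults

Two parameter bundles are provided. `paper_scale_params()` reflects the
full design (102 sensors, 500 Hz, 6 mm grid, 10,000 permutations, 10,000
bootstrap resamples). The default desk scale (`reduced_params()`), used by
the repeated-cohort simulation studies, the staged pipeline default, and
the acceptance script, is 32 sensors, 100 Hz, a 24 mm grid (~90 source
points), 96 trials per subject, 500 permutations, and 500 bootstrap
resamples; frequencies 3–6 Hz and time points covering only the valid
baseline (−1.0…−0.5 s, limited by the 1 s window) and active (0.25…0.5 s)
segments. These sizes keep a 27-subject cohort analysis near two seconds
while preserving every algorithmic property being tested (rank-2
leadfields, common filters, max-statistic clustering, balanced factorial
design). Power statements from the repeated-cohort studies are statements
about these conditions.

## Numerical choices and degenerate inputs

- Window bounds are inclusive; axis matching is exact (axes are
  constructed, not measured).
- Cluster-forming threshold uses strict `t > threshold`; observed clusters
  are independent of the permutation count (only p changes).
- Monte Carlo p is bounded below by 1/(n_perm + 1); exact mode reports the
  enumeration proportion.
- The REML variance ratio is optimised on a log grid bounded at e±12 with a
  boundary check at ρ = 0 (no subject variance).
- Degenerate rejections: empty epoch sets, single-trial conditions,
  zero/negative baseline power, all-zero paired differences, constant
  inputs to Spearman, dipoles outside (or sensors inside) the sphere,
  spacing larger than the sphere, λ ∉ [0, 1).
- Everything random is driven by explicit seeds through spawned
  `SeedSequence` trees; reports are byte-identical across repeated runs.

## What the synthetic world does not show

The conductor is a sphere shared by all subjects: no individual anatomy, no
coregistration error, no grid warping across subjects, and radial-source
silence is exact rather than approximate. Oscillations are pure sinusoids
with raised-cosine bursts — no 1/f background, no amplitude-phase coupling,
no artifact classes beyond variance outliers (no ocular/cardiac components,
no head movement). Behavioral and neural parameters are independent across
subjects except through group. Passing tests therefore demonstrate the
correctness and calibration of the *analysis machinery* under the stated
generative assumptions, not the physiological claims themselves; effect
sizes in the synthetic cohorts are deliberately strong enough for
desk-scale power and are not estimates of real-world effect sizes.
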