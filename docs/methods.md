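# Methods

## Phase portraits and continuous relative phase

Each trial is one movement cycle of sagittal joint angles (degrees, relative
to each joint's neutral position; no anatomical sign convention is imposed).
Velocity is obtained by central differences (two-point one-sided at the
ends). The phase portrait is amplitude-normalized: the angle by min–max onto
[−1, 1], the velocity by its maximum magnitude. Velocity is deliberately
*not* min–max rescaled — that would shift the phase-plane origin and bias
every phase angle.

The phase angle is the four-quadrant polar angle Φ = atan2(v_norm, x_norm)
(0° at maximum angle with zero velocity, 90° at zero angle with maximum
positive velocity), unwrapped so adjacent samples differ by < 180°.
The continuous relative phase of a (distal, proximal) coupling is
θ = Φ_distal − Φ_proximal. A second, algebraically equivalent route computes
θ in one expression, atan2(ẋ_d x_p − ẋ_p x_d, x_d x_p + ẋ_d ẋ_p) on the
normalized series — the angle of z_d·conj(z_p) with z = x + i·v. The suite
checks both routes agree pointwise to < 1e-6° on sinusoidal couplings.
A published variant of this formula with a minus sign in the denominator is
available behind `printed_denominator_sign=True` for auditing only: it
violates the defining identity that identical signals are perfectly in phase
(θ ≡ 0), so it is never used in analysis.

**Sign convention.** Under this phase definition the portrait of a physical
oscillator is traversed clockwise, so a distal waveform *delayed in time* by
Δ relative to the proximal one yields θ ≈ +Δ. Verbal lead/lag language in
the literature is not consistent about this sign; the package documents the
convention rather than guessing, and MARP is unaffected (it is even in θ).

**Branch canonicalization.** Relative phase is a circular quantity: because
each Φ is unwrapped from an arbitrary initial ±180° branch, the raw
difference can land a full 360° away from the principal value (a 43°
coupling reported as 317°). The whole θ curve is therefore shifted by the
multiple of 360° that places its median in (−180°, 180°] — shifting the
curve, never wrapping pointwise, preserves continuity. A 1e-6° guard maps a
median at exactly −180° (the anti-phase knife edge, physically identical to
+180°) to +180° so both CRP routes settle on the same branch.

Degenerate signals (constant angle, identically zero velocity, a sample at
the phase-plane origin) raise errors rather than returning silent zeros: a
frozen joint has no phase.

## Cycle grid and indices

θ is resampled by linear interpolation onto a uniform 0–100% grid of
N = 101 points (the conventional grid for gait-cycle ensemble statistics;
configurable, minimum 11). The first and last input samples map exactly to
0% and 100%. One trial is assumed to contain exactly one movement cycle,
segmented upstream; multi-cycle segmentation and gait-event detection are
out of scope.

* MARP = (1/N) Σ|θᵢ| per curve. The absolute value is applied per point, as
  the index's name and in/out-of-phase semantics require; the plain signed
  mean (which cancels symmetric excursions) is available as an audit-only
  `signed=True` variant.
* DP = (1/N) Σ SDᵢ across ≥ 2 curves on a shared grid, with the sample
  (n−1) SD, matching the small-sample inferential use of the metric.

Aggregation hierarchy: per-trial CRP → per-subject MARP (mean over that
subject's trials) and per-subject DP (pointwise SD across the subject's
trials) → group mean (SD). One scalar per subject is what gives the
t-tests their degrees of freedom (e.g. df = 12 for 7 + 7 subjects). DP for
a subject with a single trial is reported as missing, not zero — zero would
fake perfect stability. Group-level ensemble curves (pointwise mean ± SD
across all trial curves of a group/stage) are emitted separately for
visualization.

## Synthetic cohort generator

The generator emulates a three-group design — two novice groups measured
pre and post a six-week balance intervention, one professional reference
group measured once — with default sizes 7/7/14 subjects, 10 trials per
subject-stage, 200 samples per 1-s cycle, and single-harmonic joint
waveforms (amplitude 30°, baseline 10°; optional second harmonic). The
controlled quantity is the distal joint's phase delay Δ per coupling:

* subject effects: Δ_s ~ Normal(Δ_group·stage, σ_between), drawn once per
  subject per coupling and shared across stages, so pre/post comparisons are
  genuinely paired; the training effect is a stage shift of the mean offset,
  with no learning dynamics;
* trial effects: one constant phase shift per coupling per trial,
  ~ Normal(0, σ_within) — constant within the cycle so DP has the closed
  form E[DP] = c4(K)·σ_within for K trials;
* measurement noise: a smooth band-limited curve (random Fourier series on
  harmonics 2–4 of the cycle) with the requested SD, added to distal
  joints. The noise is band-limited, not white, because joint-angle records
  are smooth by construction (marker trajectories are low-pass processed
  upstream) and this pipeline performs no filtering of its own; white noise
  would be differentiated into unbounded velocity noise that no real
  kinematic trace exhibits. Harmonics ≥ 2 keep the noise orthogonal to the
  fundamental so it cannot alias into the controlled offset.

Ground truth per cell: expected MARP is the folded-normal mean
E|Normal(Δ, √(σ²_between + σ²_within))|; expected DP is c4(K)·σ_within.
Both are approximations that ignore the noise term: band-limited noise adds
a DP floor (≈ 2–4° at the preset settings) and a negligible MARP
perturbation; the DP-calibration check therefore runs noise-free, and the
cohort-level check targets MARP.

The `study_preset` ships offsets 21° (novice pre) → 40° (novice post) vs
48° (professional) for ankle–knee, and 28/31 vs 42° for knee–pelvis, with
σ_between = 6/14° (ankle–knee novice/professional) and 20/25° (knee–pelvis),
σ_within = 0.3/0.4°, noise SD 0.5°. Both novice groups draw from one
population — the design's baseline-equivalence premise — so their sampled
means differ only by chance (typically ~1–2°). The relative pattern follows
the study design this package targets (novices more in-phase than
professionals at baseline; training closes the gap; professionals slightly
more variable); the absolute scale is a package choice in degrees, since
published MARP/DP tables for this design do not state a unit. No claim is
made that the preset's units match any particular published table.

## Statistics

Shapiro–Wilk (per group) and Levene (center = mean, across groups) gate the
parametric workflow at α = 0.05; failures are reported and logged as
warnings, and the parametric analysis continues (matching the workflow the
package reproduces). A (near-)constant sample, on which Shapiro–Wilk is
undefined, is reported as an assumption failure rather than an exception.

t statistics, Welch's correction, ANOVA F and the effect sizes are computed
from their closed forms with scipy distributions supplying p-values; the
test suite cross-checks them against scipy's full reference routines
(`ttest_ind`, `ttest_rel`, `f_oneway`, `ttest_ind_from_stats`) to 1e-8.
Defaults: pooled variance (df = n₁+n₂−2), two-sided p-values, unadjusted
pairwise post hoc t-tests after ANOVA (the df pattern printed in the tables
this package audits: t(12), t(19) for groups of 7/7/14), Bonferroni
optional. `variance_policy="auto_levene"` switches to Welch when Levene
rejects homogeneity. Zero-variance edge cases: equal means give t = 0,
p = 1; unequal means set an infinite-statistic flag rather than raising.

`summary_stat_t` recomputes a pooled t-test from printed summary statistics
(means, SDs, n) for auditing published tables; reconstructed statistics can
differ from printed ones in the last digit because the summaries are
rounded, so the audit treats |Δt| ≤ 0.02 as consistent.

## Problem sizes and determinism

The acceptance script and test suite use the full 7/7/14 preset design at
200 samples/cycle, 20 seeded cohort replicates for the qualitative pattern
rate, 2000 null replicates for type-I calibration, and 100 random instances
for the statistics oracle — sizes chosen so the entire verification runs in
well under a minute while keeping Monte-Carlo noise far below the stated
tolerances. All randomness flows from explicit seeds
(`numpy.random.default_rng`); identical config + seed reproduces every
table bit-for-bit.

## Known limitations

* Single-harmonic synthetic waveforms carry a controlled phase offset but
  not the multi-harmonic shape, stance/swing asymmetry, or event-timing
  variability of real backward-running kinematics; passing recovery tests
  demonstrates correctness of the pipeline's mathematics, not robustness to
  real-world waveform complexity.
* CRP sign semantics depend on the phase-angle convention (see above);
  compare only values computed under the same convention.
* No filtering, gait-event detection, multi-cycle segmentation, or marker
  processing: the package starts from segmented single-cycle angle series.
* The gated workflow is deliberately parametric (t/ANOVA after assumption
  reporting); no nonparametric fallback is provided beyond the assumption
  report itself, and repeated-measures/mixed models are out of scope.
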