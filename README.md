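# crpcoord

Inter-joint coordination analysis for cyclic human movement (e.g. backward
running in handball defense), built on **continuous relative phase (CRP)**
from normalized phase portraits, the **MARP** and **DP** coordination
indices, and the gated parametric group-comparison workflow used in
small-sample sports-science studies. A synthetic cohort generator with known
coordination ground truth makes the whole pipeline testable without any
motion-capture data.

It is written for movement scientists and biomechanists who have per-trial
sagittal joint-angle cycles (ankle, knee, pelvis) and want per-subject
coordination metrics plus the standard three-group / two-stage statistical
report.

## The model

For a joint-angle cycle x(t) and its angular velocity ẋ(t), the phase
portrait is amplitude-normalized so joints of different ranges are
comparable:

    x_norm = 2 (x − min x)/(max x − min x) − 1 ∈ [−1, 1],   v_norm = ẋ / max|ẋ|

The phase angle is Φ = atan2(v_norm, x_norm), unwrapped over the cycle, and
the continuous relative phase of a (distal, proximal) coupling is

    θ(t) = Φ_distal(t) − Φ_proximal(t)

(θ ≡ 0 means perfectly in-phase motion). An equivalent single-expression
route computes θ = atan2(ẋ_d x_p − ẋ_p x_d, x_d x_p + ẋ_d ẋ_p) on the
normalized series; both routes agree to numerical precision on narrowband
signals and both are implemented.

Each θ curve is resampled onto a 101-point 0–100% cycle grid and summarized
by

* **MARP** = (1/N) Σ |θᵢ| — low: in-phase coupling, high: out-of-phase;
* **DP** = (1/N) Σ SDᵢ across a subject's repeated cycles — low: stable
  coordination, high: variable.

Per-subject MARP/DP feed Shapiro–Wilk and Levene assumption checks, pooled
independent and paired t-tests, one-way ANOVA with pairwise post hoc
t-tests, and Cohen's d / η² effect sizes.

## Worked example

Simulate the default three-group cohort (7 + 7 novices with pre/post stages,
14 professionals, 10 trials per subject-stage) and analyze it:

```
crpcoord simulate --seed 7 --out cohort
crpcoord analyze --manifest cohort/manifest.csv --out report
```

which prints the group summary (means with SD, degrees):

```
  group  stage    coupling  n  marp_mean   marp_sd  dp_mean    dp_sd
control   post  ankle-knee  7  39.010757  3.732896 3.535626 0.499912
control    pre  ankle-knee  7  20.044993  3.817227 3.520957 0.232149
 target single  ankle-knee 14  44.205705 14.752571 3.679967 0.359471
   test   post  ankle-knee  7  41.401316  4.834395 3.631171 0.490920
   test    pre  ankle-knee  7  22.504971  4.786239 3.916677 0.503455
...
```

Read: before training both novice groups are clearly more in-phase at the
ankle–knee coupling (MARP ≈ 20–22°) than the professionals (≈ 44°); after
training they move toward the professional, more out-of-phase level
(≈ 39–41°). `report/` also contains the per-subject metrics, assumption
report, all test tables, ensemble mean±SD CRP curves, and figures.

The audit verb recomputes a pooled t-test from printed summary statistics,
e.g. two groups of 7 with MARP 1.79 (0.55) and 1.62 (0.46):

```
$ crpcoord audit --mean1 1.79 --sd1 0.55 --n1 7 --mean2 1.62 --sd2 0.46 --n2 7 --printed-t 0.64
t(12) = 0.6273, p = 0.5422, d = 0.3353
printed t = 0.64: |Δt| = 0.0127 -> consistent
```

The same functionality is available as a library (`crpcoord.compute_crp`,
`crpcoord.marp`, `crpcoord.deviation_phase`, `crpcoord.analyze_cohort`, …).

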