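"""Synthetic kinematic cohorts with known coordination ground truth.

The generator emulates a three-group (control / test novices, professional
target), two-stage (pre / post training; single for the target) study of
backward running. Each trial is one movement cycle of sinusoidal sagittal
joint-angle curves in which the distal joint of every coupling is delayed in
phase by a controlled offset Δ, so the pipeline's CRP ≈ Δ and MARP ≈ |Δ| by
construction:

    proximal(t) = A sin(2πt/T) + baseline
    distal(t)   = A sin(2πt/T − Δ_s − jitter_k) + baseline + noise

Randomness enters at three levels, each with a closed-form consequence:
subject offsets Δ_s ~ Normal(Δ_group, σ_between) (between-subject spread),
a per-trial constant phase shift jitter_k ~ Normal(0, σ_within) (so DP has
the c4-corrected closed form c4(K)·σ_within), and additive angle noise.

The noise is band-limited — a random low-order Fourier curve with the
requested SD — not white: joint-angle records are smooth by nature (marker
trajectories are low-pass processed upstream), and a derivative-based phase
pipeline that performs no filtering of its own would turn per-sample white
noise into unbounded velocity noise, which no real kinematic trace exhibits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import erf

from .errors import ValidationError
from .io import AngleTrial, CohortManifest, Coupling, DEFAULT_COUPLINGS, write_manifest, write_trial_table
from .metrics import c4

__all__ = [
    "ConditionParams",
    "SimParams",
    "GroundTruth",
    "CohortDataset",
    "simulate_joint_cycle",
    "simulate_cohort",
    "ground_truth",
    "study_preset",
    "folded_normal_mean",
]

#: per-group demographic constants used for simulated manifests (years, m, kg)
_DEMOGRAPHICS = {
    "control": (21.0, 1.70, 75.0),
    "test": (22.0, 1.75, 73.0),
    "target": (21.0, 1.72, 74.0),
}

_GROUP_STAGES = {"control": ("pre", "post"), "test": ("pre", "post"), "target": ("single",)}
_GROUP_PREFIX = {"control": "C", "test": "T", "target": "P"}


@dataclass(frozen=True)
class ConditionParams:
    """Effect structure of one (group, stage) cell.

    offsets
        mean inter-joint phase delay Δ of the distal joint per coupling (deg).
    sigma_between
        between-subject SD of Δ (deg); scalar or per-coupling mapping.
    sigma_within
        cycle-to-cycle SD of the per-trial constant phase shift (deg).
    sigma_noise
        SD of the band-limited additive angle noise on distal joints (deg).
    """

    offsets: Mapping[Coupling, float]
    sigma_between: float | Mapping[Coupling, float] = 0.0
    sigma_within: float = 0.0
    sigma_noise: float = 0.0

    def __post_init__(self):
        object.__setattr__(
            self, "offsets", {tuple(k): float(v) for k, v in self.offsets.items()}
        )
        for c, d in self.offsets.items():
            if not -180.0 < d < 180.0:
                raise ValidationError(f"offset for {c} must be in (-180, 180), got {d}")
        for c in self.offsets:
            if self.sb(c) < 0:
                raise ValidationError("sigma_between must be >= 0")
        if self.sigma_within < 0 or self.sigma_noise < 0:
            raise ValidationError("jitter/noise SDs must be >= 0")

    def sb(self, coupling: Coupling) -> float:
        if isinstance(self.sigma_between, Mapping):
            return float(self.sigma_between[tuple(coupling)])
        return float(self.sigma_between)


@dataclass(frozen=True)
class SimParams:
    """Full design of a simulated cohort."""

    conditions: Mapping[tuple[str, str], ConditionParams]
    n_subjects: Mapping[str, int] = field(
        default_factory=lambda: {"control": 7, "test": 7, "target": 14}
    )
    trials_per_subject: int = 10
    samples_per_cycle: int = 200
    cycle_duration_s: float = 1.0
    amplitude_deg: float = 30.0
    baseline_deg: float = 10.0
    second_harmonic: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "conditions", {tuple(k): v for k, v in self.conditions.items()}
        )
        for group, n in self.n_subjects.items():
            if n < 2:
                raise ValidationError(f"need >= 2 subjects per group, got {n} for {group}")
        for group in self.n_subjects:
            for stage in _GROUP_STAGES[group]:
                if (group, stage) not in self.conditions:
                    raise ValidationError(f"no ConditionParams for ({group}, {stage})")
        if self.trials_per_subject < 1:
            raise ValidationError("trials_per_subject must be >= 1")
        if self.samples_per_cycle < 16:
            raise ValidationError("samples_per_cycle must be >= 16 (undersampled phase)")

    @property
    def couplings(self) -> tuple[Coupling, ...]:
        first = next(iter(self.conditions.values()))
        return tuple(first.offsets)


@dataclass(frozen=True)
class GroundTruth:
    """Expected MARP and DP per (group, stage, coupling) implied by SimParams."""

    expected: Mapping[tuple[str, str], Mapping[Coupling, Mapping[str, float]]]

    def marp(self, group: str, stage: str, coupling: Coupling) -> float:
        return self.expected[(group, stage)][tuple(coupling)]["marp"]

    def dp(self, group: str, stage: str, coupling: Coupling) -> float:
        return self.expected[(group, stage)][tuple(coupling)]["dp"]

    def to_json(self) -> dict:
        return {
            f"{g}/{s}": {f"{c[0]}-{c[1]}": dict(v) for c, v in percell.items()}
            for (g, s), percell in self.expected.items()
        }


@dataclass
class CohortDataset:
    """Simulated trials plus their manifest and generating ground truth."""

    trials: list[AngleTrial]
    manifest: CohortManifest
    truth: GroundTruth
    params: SimParams

    def write(self, out_dir) -> None:
        """Materialize the cohort as the CSV trial/manifest formats io reads."""
        import pathlib

        out = pathlib.Path(out_dir)
        (out / "trials").mkdir(parents=True, exist_ok=True)
        paths = dict(zip(
            self.manifest.records.index,
            self.manifest.records["trial_path"],
        ))
        for trial, row_path in zip(self.trials, self.manifest.records["trial_path"]):
            write_trial_table(trial, out / row_path)
        write_manifest(self.manifest, out / "manifest.csv")
        from .io import write_json

        write_json(self.truth.to_json(), out / "ground_truth.json")


# ---------------------------------------------------------------------------
# Waveform construction


def _joint_lags(offsets: Mapping[Coupling, float]) -> dict[str, float]:
    """Resolve per-joint phase lags from per-coupling distal delays.

    The proximal-most joint of the coupling chain gets lag 0; each coupling
    (distal, proximal) sets lag[distal] = lag[proximal] + Δ.
    """
    joints = {j for c in offsets for j in c}
    distals = {d for d, _ in offsets}
    roots = joints - distals
    if not roots:
        raise ValidationError("couplings contain a cycle; no proximal-most joint")
    lags = {r: 0.0 for r in roots}
    pending = dict(offsets)
    while pending:
        progressed = False
        for (d, p), delta in list(pending.items()):
            if p in lags:
                lags[d] = lags[p] + delta
                del pending[(d, p)]
                progressed = True
        if not progressed:
            raise ValidationError(f"couplings do not form a connected chain: {pending}")
    return lags


_NOISE_HARMONICS = (2, 3, 4)


def _bandlimited_noise(omega_t: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth zero-mean noise curve with time-averaged SD sigma (expected).

    Random Fourier series over harmonics 2–4 of the cycle: smooth enough that
    its derivative stays bounded, and orthogonal to the fundamental so it does
    not alias into the controlled phase offset.
    """
    m = len(_NOISE_HARMONICS)
    coef_sd = sigma / math.sqrt(m)
    noise = np.zeros_like(omega_t)
    for k in _NOISE_HARMONICS:
        a, b = rng.normal(0.0, coef_sd, size=2)
        noise += a * np.cos(k * omega_t) + b * np.sin(k * omega_t)
    return noise


def simulate_joint_cycle(
    delta: float | Mapping[Coupling, float],
    sigma_within: float = 0.0,
    sigma_noise: float = 0.0,
    n_samples: int = 200,
    rng: np.random.Generator | None = None,
    *,
    subject_id: str = "S01",
    group: str = "control",
    stage: str = "pre",
    trial_index: int = 1,
    cycle_duration_s: float = 1.0,
    amplitude_deg: float = 30.0,
    baseline_deg: float = 10.0,
    second_harmonic: float = 0.0,
) -> AngleTrial:
    """Generate one full-cycle trial with a known distal phase delay per coupling.

    ``delta`` may be a scalar (applied to every default coupling) or a mapping
    coupling → delay in degrees. The jitter draw is one constant phase shift
    per coupling for the whole trial; noise is a smooth band-limited random
    curve (harmonics 2–4 of the cycle) of SD ``sigma_noise`` on distal joints.
    """
    if n_samples < 16:
        raise ValidationError("n_samples must be >= 16 (undersampled phase)")
    rng = rng or np.random.default_rng(0)
    if not isinstance(delta, Mapping):
        delta = {c: float(delta) for c in DEFAULT_COUPLINGS}
    jittered = {
        c: d + (rng.normal(0.0, sigma_within) if sigma_within > 0 else 0.0)
        for c, d in delta.items()
    }
    lags = _joint_lags(jittered)
    distal_joints = {d for d, _ in delta}
    t = np.linspace(0.0, cycle_duration_s, n_samples)
    omega_t = 2.0 * np.pi * t / cycle_duration_s
    angles = {}
    for joint, lag in lags.items():
        phase = omega_t - math.radians(lag)
        wave = np.sin(phase)
        if second_harmonic:
            wave = wave + second_harmonic * np.sin(2.0 * phase)
        series = amplitude_deg * wave + baseline_deg
        if sigma_noise > 0 and joint in distal_joints:
            series = series + _bandlimited_noise(omega_t, sigma_noise, rng)
        angles[joint] = series
    return AngleTrial(
        subject_id=subject_id,
        group=group,
        stage=stage,
        trial_index=trial_index,
        sample_rate=(n_samples - 1) / cycle_duration_s,
        time=t,
        angles=angles,
    )


def simulate_cohort(sim: SimParams) -> CohortDataset:
    """Draw the full cohort: subjects, stages and trials, with manifest and truth.

    Subject-level offsets are Δ_s = Δ(group, stage) + b_s with a per-subject,
    per-coupling random effect b_s ~ Normal(0, σ_between) shared across stages,
    so pre/post comparisons are genuinely paired.
    """
    rng = np.random.default_rng(sim.seed)
    trials: list[AngleTrial] = []
    rows = []
    for group in ("control", "test", "target"):
        if group not in sim.n_subjects:
            continue
        stages = _GROUP_STAGES[group]
        base_cond = sim.conditions[(group, stages[0])]
        age, height, weight = _DEMOGRAPHICS[group]
        for s_idx in range(sim.n_subjects[group]):
            subject_id = f"{_GROUP_PREFIX[group]}{s_idx + 1:02d}"
            b_s = {c: rng.normal(0.0, base_cond.sb(c)) for c in sim.couplings}
            for stage in stages:
                cond = sim.conditions[(group, stage)]
                delta_s = {c: cond.offsets[c] + b_s[c] for c in sim.couplings}
                for k in range(1, sim.trials_per_subject + 1):
                    trial = simulate_joint_cycle(
                        delta_s,
                        cond.sigma_within,
                        cond.sigma_noise,
                        sim.samples_per_cycle,
                        rng,
                        subject_id=subject_id,
                        group=group,
                        stage=stage,
                        trial_index=k,
                        cycle_duration_s=sim.cycle_duration_s,
                        amplitude_deg=sim.amplitude_deg,
                        baseline_deg=sim.baseline_deg,
                        second_harmonic=sim.second_harmonic,
                    )
                    trials.append(trial)
                    rows.append(
                        {
                            "subject_id": subject_id,
                            "group": group,
                            "stage": stage,
                            "trial_path": f"trials/{subject_id}_{stage}_{k:02d}.csv",
                            "age_y": age,
                            "height_m": height,
                            "weight_kg": weight,
                        }
                    )
    import pandas as pd

    manifest = CohortManifest(pd.DataFrame(rows))
    return CohortDataset(
        trials=trials, manifest=manifest, truth=ground_truth(sim), params=sim
    )


# ---------------------------------------------------------------------------
# Ground truth


def folded_normal_mean(mu: float, sigma: float) -> float:
    """E|X| for X ~ Normal(mu, sigma); reduces to |mu| when sigma = 0."""
    if sigma == 0.0:
        return abs(mu)
    return sigma * math.sqrt(2.0 / math.pi) * math.exp(
        -(mu**2) / (2.0 * sigma**2)
    ) + mu * float(erf(mu / (sigma * math.sqrt(2.0))))


def ground_truth(sim: SimParams) -> GroundTruth:
    """Expected MARP and DP per cell under the constant-phase-shift model.

    A subject-stage CRP curve is ≈ constant at Δ_s + jitter_k, so the expected
    per-subject MARP is the folded-normal mean E|Normal(Δ, √(σ_b²+σ_w²))| and
    the expected DP across K trials is the c4-corrected SD expectation
    c4(K)·σ_w (NaN when K < 2, where DP is undefined).
    """
    K = sim.trials_per_subject
    expected: dict = {}
    for (group, stage), cond in sim.conditions.items():
        percell = {}
        for coupling, delta in cond.offsets.items():
            s = math.hypot(cond.sb(coupling), cond.sigma_within)
            exp_marp = folded_normal_mean(abs(delta), s)
            if K < 2:
                exp_dp = math.nan
            elif cond.sigma_within == 0.0:
                exp_dp = 0.0
            else:
                exp_dp = c4(K) * cond.sigma_within
            percell[coupling] = {"marp": exp_marp, "dp": exp_dp}
        expected[(group, stage)] = percell
    return GroundTruth(expected=expected)


# ---------------------------------------------------------------------------
# Study-design preset


def study_preset(seed: int = 0, **overrides) -> SimParams:
    """Cohort preset mirroring the study design: 7/7/14 subjects, two stages.

    Both novice groups are drawn from one population (the design's baseline-
    equivalence premise), starting with relatively in-phase ankle–knee
    coordination; training shifts both toward the professionals' more
    out-of-phase level. Professionals also carry slightly higher
    cycle-to-cycle variability (DP). Offsets are in degrees; the relative
    pattern across cells follows the study's reported index ratios.
    """
    ak = ("ankle", "knee")
    kp = ("knee", "pelvis")
    novice_sb = {ak: 6.0, kp: 20.0}
    target_sb = {ak: 14.0, kp: 25.0}
    novice_pre = ConditionParams(
        offsets={ak: 21.0, kp: 28.0}, sigma_between=novice_sb,
        sigma_within=0.3, sigma_noise=0.5,
    )
    novice_post = ConditionParams(
        offsets={ak: 40.0, kp: 31.0}, sigma_between=novice_sb,
        sigma_within=0.3, sigma_noise=0.5,
    )
    conditions = {
        ("control", "pre"): novice_pre,
        ("control", "post"): novice_post,
        ("test", "pre"): novice_pre,
        ("test", "post"): novice_post,
        ("target", "single"): ConditionParams(
            offsets={ak: 48.0, kp: 42.0}, sigma_between=target_sb,
            sigma_within=0.4, sigma_noise=0.5,
        ),
    }
    kwargs = dict(conditions=conditions, seed=seed)
    kwargs.update(overrides)
    return SimParams(**kwargs)
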