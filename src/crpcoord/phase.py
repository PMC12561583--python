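"""Phase portraits and continuous relative phase (CRP).

A joint-angle series x(t) and its angular velocity ẋ(t) are amplitude-
normalized so the phase-plane trajectory (x_norm, v_norm) is comparable
across joints and subjects::

    x_norm = 2 (x − min x) / (max x − min x) − 1      ∈ [−1, 1]
    v_norm = ẋ / max|ẋ|                               ∈ [−1, 1]

The phase angle is the four-quadrant polar angle of a phase-plane point,
Φ = atan2(v_norm, x_norm), unwrapped along the cycle; the continuous relative
phase of a (distal, proximal) coupling is θ = Φ_distal − Φ_proximal. θ ≡ 0
means the joints move perfectly in phase; larger |θ| means more out-of-phase
coordination. Under this convention a distal joint whose waveform is delayed
in time by Δ relative to the proximal one yields θ ≈ +Δ for near-sinusoidal
signals.

A direct single-expression route computes the same quantity from two raw
series:  θ = atan2(ẋ_d·x_p − ẋ_p·x_d,  x_d·x_p + ẋ_d·ẋ_p)  on the
normalized series, which is the angle of z_d · conj(z_p) with z = x + i·v.
The two routes agree to numerical precision on narrowband signals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DegenerateSignalError, UndefinedPhaseError, ValidationError
from .io import AngleTrial, Coupling

__all__ = [
    "NormalizedCycle",
    "PhaseTrajectory",
    "CRPCurve",
    "differentiate",
    "normalize_amplitude",
    "phase_angle",
    "phase_trajectory",
    "relative_phase",
    "relative_phase_direct",
    "time_normalize",
    "compute_crp",
]


@dataclass(frozen=True)
class NormalizedCycle:
    """A series resampled onto the uniform 0–100% movement-cycle grid."""

    n_points: int
    cycle_fraction: np.ndarray  # percent, 0..100 inclusive
    values: np.ndarray


@dataclass(frozen=True)
class PhaseTrajectory:
    """Amplitude-normalized phase-plane trajectory and its unwrapped phase angle."""

    x_norm: np.ndarray
    v_norm: np.ndarray
    phi: np.ndarray  # degrees, unwrapped


@dataclass(frozen=True)
class CRPCurve:
    """Continuous relative phase of one coupling over the normalized cycle."""

    coupling: Coupling
    cycle_fraction: np.ndarray
    theta: np.ndarray  # degrees
    subject_id: str = ""
    group: str = ""
    stage: str = ""
    trial_index: int = 0


def differentiate(series, dt: float) -> np.ndarray:
    """First time derivative: central differences interior, 2-point one-sided ends."""
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        raise ValidationError(f"need >= 3 samples to differentiate, got {x.size}")
    if dt <= 0:
        raise ValidationError("dt must be > 0")
    return np.gradient(x, dt, edge_order=1)


def normalize_amplitude(angle, velocity) -> tuple[np.ndarray, np.ndarray]:
    """Map the angle to [−1, 1] by min–max and scale velocity by its max magnitude.

    Velocity keeps its sign (scaled by max|v|, not min–max rescaled) so the
    phase-plane origin is not shifted.
    """
    x = np.asarray(angle, dtype=float)
    v = np.asarray(velocity, dtype=float)
    rng = x.max() - x.min()
    if rng <= 0:
        raise DegenerateSignalError("constant angle series has no phase (zero range)")
    vmax = np.abs(v).max()
    if vmax <= 0:
        raise DegenerateSignalError("identically zero velocity has no phase")
    x_norm = 2.0 * (x - x.min()) / rng - 1.0
    v_norm = v / vmax
    return x_norm, v_norm


def phase_angle(x_norm, v_norm) -> np.ndarray:
    """Unwrapped phase angle (degrees) of the phase-plane points (x_norm, v_norm).

    0° at (1, 0) — maximum angle, zero velocity — and 90° at (0, 1).
    """
    x = np.asarray(x_norm, dtype=float)
    v = np.asarray(v_norm, dtype=float)
    if x.shape != v.shape:
        raise ValidationError("x_norm and v_norm must have equal length")
    at_origin = (x == 0.0) & (v == 0.0)
    if at_origin.any():
        raise UndefinedPhaseError(np.flatnonzero(at_origin))
    return np.degrees(np.unwrap(np.arctan2(v, x)))


def phase_trajectory(angle, dt: float) -> PhaseTrajectory:
    """Build the normalized phase portrait of one joint-angle series."""
    v = differentiate(angle, dt)
    x_norm, v_norm = normalize_amplitude(angle, v)
    return PhaseTrajectory(x_norm=x_norm, v_norm=v_norm, phi=phase_angle(x_norm, v_norm))


def _canonical_branch(theta: np.ndarray) -> np.ndarray:
    """Shift a continuous relative-phase curve by a multiple of 360° so its
    median lies in (−180°, 180°].

    Relative phase is defined modulo 360°; because the two phase angles are
    each unwrapped from an arbitrary initial branch, their difference can come
    out offset by ±360°. Shifting the whole curve (never pointwise wrapping)
    keeps it continuous.
    """
    med = float(np.median(theta))
    # median in (-180, 180]; the 1e-6 guard sends a median at -180 (the
    # anti-phase knife edge, same physical phase as +180) to +180 so both
    # CRP routes settle on the same branch
    shift = math.ceil((med - 180.0 - 1e-6) / 360.0) * 360.0
    return theta - shift


def relative_phase(phi_distal, phi_proximal) -> np.ndarray:
    """Continuous relative phase θ = Φ_distal − Φ_proximal (degrees).

    The returned curve is branch-canonicalized: shifted by the multiple of
    360° that brings its median into (−180°, 180°].
    """
    a = np.asarray(phi_distal, dtype=float)
    b = np.asarray(phi_proximal, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(
            f"phase series length mismatch: {a.shape} vs {b.shape}"
        )
    return _canonical_branch(a - b)


def relative_phase_direct(
    x_distal, x_proximal, dt: float, *, printed_denominator_sign: bool = False
) -> np.ndarray:
    """CRP in one expression from two raw angle series (degrees, unwrapped).

    Computes atan2(ẋ_d·x_p − ẋ_p·x_d, x_d·x_p + ẋ_d·ẋ_p) on amplitude-
    normalized series. ``printed_denominator_sign=True`` flips the denominator
    to x_d·x_p − ẋ_d·ẋ_p, an audit-only variant that does not satisfy the
    in-phase identity (identical inputs no longer give θ ≡ 0).
    """
    x1 = np.asarray(x_distal, dtype=float)
    x2 = np.asarray(x_proximal, dtype=float)
    if x1.shape != x2.shape:
        raise ValidationError("series length mismatch")
    v1 = differentiate(x1, dt)
    v2 = differentiate(x2, dt)
    x1n, v1n = normalize_amplitude(x1, v1)
    x2n, v2n = normalize_amplitude(x2, v2)
    num = v1n * x2n - v2n * x1n
    den = x1n * x2n - v1n * v2n if printed_denominator_sign else x1n * x2n + v1n * v2n
    return _canonical_branch(np.degrees(np.unwrap(np.arctan2(num, den))))


def time_normalize(series, n_points: int = 101) -> NormalizedCycle:
    """Resample a uniformly sampled cycle onto the 0–100% grid (linear interpolation).

    The first and last input samples map exactly to 0% and 100%.
    """
    if n_points < 11:
        raise ConfigError(f"n_points must be >= 11, got {n_points}")
    y = np.asarray(series, dtype=float)
    if y.size < 4:
        raise ValidationError(f"need >= 4 samples to time-normalize, got {y.size}")
    grid = np.linspace(0.0, 100.0, n_points)
    src = np.linspace(0.0, 100.0, y.size)
    return NormalizedCycle(
        n_points=n_points, cycle_fraction=grid, values=np.interp(grid, src, y)
    )


def compute_crp(
    trial: AngleTrial,
    coupling: Coupling,
    n_points: int = 101,
    *,
    method: str = "phase_angle",
) -> CRPCurve:
    """CRP curve of one coupling for one trial, on the normalized cycle grid.

    ``method`` selects the route: "phase_angle" differences the two unwrapped
    phase-plane angles; "direct" evaluates the single-expression form. Both
    agree to numerical precision on narrowband signals.
    """
    distal, proximal = coupling
    for joint in (distal, proximal):
        if joint not in trial.angles:
            raise ValidationError(f"trial has no joint {joint!r}")
    dt = trial.dt
    if method == "phase_angle":
        phi_d = phase_trajectory(trial.angles[distal], dt).phi
        phi_p = phase_trajectory(trial.angles[proximal], dt).phi
        theta = relative_phase(phi_d, phi_p)
    elif method == "direct":
        theta = relative_phase_direct(trial.angles[distal], trial.angles[proximal], dt)
    else:
        raise ConfigError(f"unknown CRP method {method!r}")
    cyc = time_normalize(theta, n_points)
    return CRPCurve(
        coupling=(distal, proximal),
        cycle_fraction=cyc.cycle_fraction,
        theta=cyc.values,
        subject_id=trial.subject_id,
        group=trial.group,
        stage=trial.stage,
        trial_index=trial.trial_index,
    )
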