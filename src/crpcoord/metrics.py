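"""MARP and DP coordination indices and ensemble CRP curves.

MARP (mean absolute relative phase) summarizes one CRP curve:
MARP = (1/N) Σ |θ_i| over the N cycle grid points — low values mean the
coupling moves in phase, high values out of phase.

DP (deviation phase) summarizes variability across repeated curves:
DP = (1/N) Σ SD_i, where SD_i is the sample standard deviation of θ_i across
curves at grid point i — low values mean stable coordination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InsufficientReplicatesError, ValidationError
from .io import AnalysisConfig, AngleTrial, Coupling
from .phase import CRPCurve, compute_crp

__all__ = [
    "CouplingMetrics",
    "EnsembleCurve",
    "marp",
    "deviation_phase",
    "ensemble_curve",
    "subject_coupling_metrics",
    "c4",
]


@dataclass(frozen=True)
class CouplingMetrics:
    """Per-subject MARP and DP for one coupling and stage.

    ``dp`` is NaN when fewer than two cycles were available: a single trial
    carries no variability information (zero would fake perfect stability).
    """

    subject_id: str
    group: str
    stage: str
    coupling: Coupling
    marp: float
    dp: float
    n_cycles: int


@dataclass(frozen=True)
class EnsembleCurve:
    """Pointwise mean ± sample SD of CRP curves over the 0–100% cycle grid."""

    coupling: Coupling
    cycle_fraction: np.ndarray
    mean_theta: np.ndarray
    sd_theta: np.ndarray
    n: int


def _theta(curve) -> np.ndarray:
    return np.asarray(curve.theta if isinstance(curve, CRPCurve) else curve, dtype=float)


def marp(curve, *, signed: bool = False) -> float:
    """Mean absolute relative phase of one CRP curve.

    ``signed=True`` is an audit-only variant averaging θ_i without the
    absolute value (the plain mean, which can cancel out-of-phase excursions).
    """
    theta = _theta(curve)
    if theta.size == 0:
        raise ValidationError("cannot compute MARP of an empty curve")
    if not np.all(np.isfinite(theta)):
        raise ValidationError("CRP curve contains non-finite values")
    return float(np.mean(theta) if signed else np.mean(np.abs(theta)))


def _stack(curves: Sequence) -> np.ndarray:
    if len(curves) < 2:
        raise InsufficientReplicatesError(
            f"need >= 2 curves, got {len(curves)}"
        )
    thetas = [_theta(c) for c in curves]
    n = thetas[0].size
    if any(t.size != n for t in thetas):
        raise ValidationError("curves are not on a common grid")
    real = [c for c in curves if isinstance(c, CRPCurve)]
    if real:
        coupling = real[0].coupling
        if any(c.coupling != coupling for c in real):
            raise ValidationError("curves mix different couplings")
        grids = [c.cycle_fraction for c in real]
        if any(g.size != grids[0].size or not np.allclose(g, grids[0]) for g in grids):
            raise ValidationError("curves are not on a common cycle grid")
    return np.vstack(thetas)


def deviation_phase(curves: Sequence) -> float:
    """DP = mean over grid points of the across-curve sample SD (ddof=1)."""
    stacked = _stack(curves)
    return float(np.mean(np.std(stacked, axis=0, ddof=1)))


def ensemble_curve(curves: Sequence[CRPCurve]) -> EnsembleCurve:
    """Pointwise mean and sample SD across >= 2 CRP curves on a shared grid."""
    stacked = _stack(curves)
    first = next(c for c in curves if isinstance(c, CRPCurve))
    return EnsembleCurve(
        coupling=first.coupling,
        cycle_fraction=first.cycle_fraction.copy(),
        mean_theta=stacked.mean(axis=0),
        sd_theta=np.std(stacked, axis=0, ddof=1),
        n=stacked.shape[0],
    )


def subject_coupling_metrics(
    trials: Sequence[AngleTrial],
    coupling: Coupling,
    config: AnalysisConfig | None = None,
) -> CouplingMetrics:
    """Aggregate one subject/stage: per-trial CRP → mean MARP and across-trial DP."""
    if not trials:
        raise ValidationError("no trials supplied")
    config = config or AnalysisConfig()
    first = trials[0]
    if any(
        (t.subject_id, t.group, t.stage) != (first.subject_id, first.group, first.stage)
        for t in trials
    ):
        raise ValidationError("trials mix subjects, groups or stages")
    curves = [compute_crp(t, coupling, config.n_cycle_points) for t in trials]
    marp_value = float(np.mean([marp(c) for c in curves]))
    dp_value = deviation_phase(curves) if len(curves) >= 2 else math.nan
    if config.angle_unit_out == "radians":
        marp_value = math.radians(marp_value)
        dp_value = math.radians(dp_value) if math.isfinite(dp_value) else dp_value
    return CouplingMetrics(
        subject_id=first.subject_id,
        group=first.group,
        stage=first.stage,
        coupling=tuple(coupling),
        marp=marp_value,
        dp=dp_value,
        n_cycles=len(curves),
    )


def c4(n: int) -> float:
    """Unbiasing constant of the sample SD: E[SD] = c4(n)·σ for iid normal data."""
    if n < 2:
        raise ValidationError("c4 requires n >= 2")
    return math.sqrt(2.0 / (n - 1)) * math.gamma(n / 2.0) / math.gamma((n - 1) / 2.0)
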