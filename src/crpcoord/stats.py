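"""Gated parametric group comparisons on per-subject coordination metrics.

The workflow mirrors small-sample sports-science practice: Shapiro–Wilk
normality and Levene homogeneity checks at α, then pooled-variance t-tests
(independent and paired), one-way ANOVA with unadjusted pairwise post hoc
t-tests, and standardized effect sizes (Cohen's d for t, η² for ANOVA).
Assumption failures are reported, not silently acted on; the analysis is
parametric throughout unless ``variance_policy`` requests Welch on Levene
failure.

Test statistics are assembled from their closed forms; p-values come from
scipy's t and F distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "StatsResult",
    "AssumptionReport",
    "assumption_gate",
    "independent_t",
    "summary_stat_t",
    "paired_t",
    "one_way_anova",
    "posthoc_pairwise",
    "cohens_d",
]


@dataclass(frozen=True)
class StatsResult:
    """One inferential test: statistic, df, p, effect size and provenance."""

    test: str
    statistic: float
    df: float | tuple[float, float]
    p: float
    effect_size: float
    effect_size_type: str
    groups: tuple[str, ...] = ()
    n: tuple[int, ...] = ()
    note: str = ""

    @property
    def infinite(self) -> bool:
        return math.isinf(self.statistic)


@dataclass(frozen=True)
class AssumptionReport:
    """Shapiro–Wilk per group and Levene across groups, flagged at alpha."""

    alpha: float
    shapiro: Mapping[str, tuple[float, float, bool]]  # label -> (W, p, passed)
    levene: tuple[float, float, bool] | None  # (stat, p, passed); None if < 2 groups

    @property
    def all_passed(self) -> bool:
        ok = all(passed for _, _, passed in self.shapiro.values())
        if self.levene is not None:
            ok = ok and self.levene[2]
        return ok


def _as_arrays(groups) -> tuple[list[str], list[np.ndarray]]:
    if isinstance(groups, Mapping):
        labels = list(groups)
        arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    else:
        labels = [f"group{i + 1}" for i in range(len(groups))]
        arrays = [np.asarray(g, dtype=float) for g in groups]
    return labels, arrays


def assumption_gate(groups, alpha: float = 0.05) -> AssumptionReport:
    """Normality (Shapiro–Wilk, per group) and variance homogeneity (Levene).

    Levene uses the mean as center (the classical test). A constant sample,
    on which Shapiro–Wilk is undefined, is reported as an assumption failure
    rather than raising.
    """
    labels, arrays = _as_arrays(groups)
    for lab, a in zip(labels, arrays):
        if a.size < 3:
            raise ValidationError(f"group {lab!r} has n={a.size} < 3")
    shapiro = {}
    for lab, a in zip(labels, arrays):
        # (near-)constant samples: Shapiro-Wilk is undefined; report as failure
        if np.ptp(a) <= 1e-10 * max(1.0, float(np.max(np.abs(a)))):
            shapiro[lab] = (math.nan, math.nan, False)
            continue
        w, p = sps.shapiro(a)
        shapiro[lab] = (float(w), float(p), bool(p > alpha))
    levene = None
    if len(arrays) >= 2:
        if all(np.ptp(a) == 0.0 for a in arrays):
            levene = (math.nan, math.nan, False)
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                stat, p = sps.levene(*arrays, center="mean")
            levene = (float(stat), float(p), bool(p > alpha))
    return AssumptionReport(alpha=alpha, shapiro=shapiro, levene=levene)


def cohens_d(g1, g2) -> float:
    """Cohen's d with the pooled SD (independent samples)."""
    a, b = np.asarray(g1, dtype=float), np.asarray(g2, dtype=float)
    n1, n2 = a.size, b.size
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0.0:
        return 0.0 if a.mean() == b.mean() else math.inf
    return float((a.mean() - b.mean()) / math.sqrt(sp2))


def independent_t(
    g1,
    g2,
    variance_policy: str = "pooled",
    *,
    alpha: float = 0.05,
    labels: tuple[str, str] = ("group1", "group2"),
) -> StatsResult:
    """Two-sample t-test; pooled df = n1+n2−2 by default, Welch optional.

    ``variance_policy='auto_levene'`` runs Levene at ``alpha`` and switches to
    Welch when homogeneity is rejected. Effect size is Cohen's d (pooled SD).
    Two zero-variance samples with equal means give t = 0, p = 1; with unequal
    means the statistic is flagged infinite.
    """
    a, b = np.asarray(g1, dtype=float), np.asarray(g2, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValidationError("need n >= 2 in both groups")
    if variance_policy == "auto_levene":
        _, lev_p = sps.levene(a, b, center="mean")
        variance_policy = "welch" if lev_p <= alpha else "pooled"
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if v1 == 0.0 and v2 == 0.0:
        if diff == 0.0:
            return StatsResult(
                "independent_t", 0.0, float(n1 + n2 - 2), 1.0, 0.0, "cohens_d",
                labels, (n1, n2),
            )
        return StatsResult(
            "independent_t", math.copysign(math.inf, diff), float(n1 + n2 - 2),
            0.0, math.inf, "cohens_d", labels, (n1, n2),
            note="zero variance with unequal means",
        )
    if variance_policy == "pooled":
        df = float(n1 + n2 - 2)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    elif variance_policy == "welch":
        se = math.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    else:
        raise ValidationError(f"unknown variance_policy {variance_policy!r}")
    t = diff / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return StatsResult(
        "independent_t", float(t), df, p, cohens_d(a, b), "cohens_d", labels, (n1, n2)
    )


def summary_stat_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    *, labels: tuple[str, str] = ("group1", "group2"),
) -> StatsResult:
    """Pooled-variance t from summary statistics (audit tool for printed tables).

    Identical to ``independent_t`` applied to raw data with these summaries.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValidationError("SDs must be >= 0")
    if n1 < 2 or n2 < 2:
        raise ValidationError("need n >= 2 in both groups")
    df = float(n1 + n2 - 2)
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    diff = mean1 - mean2
    if sp2 == 0.0:
        if diff == 0.0:
            return StatsResult("summary_stat_t", 0.0, df, 1.0, 0.0, "cohens_d",
                               labels, (n1, n2))
        return StatsResult("summary_stat_t", math.copysign(math.inf, diff), df, 0.0,
                           math.inf, "cohens_d", labels, (n1, n2),
                           note="zero variance with unequal means")
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = diff / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    d = diff / math.sqrt(sp2)
    return StatsResult("summary_stat_t", float(t), df, p, float(d), "cohens_d",
                       labels, (n1, n2))


def paired_t(pre, post, *, labels: tuple[str, str] = ("pre", "post")) -> StatsResult:
    """Paired t on subject-matched differences (post − pre), df = n − 1.

    Effect size is Cohen's d_z = mean(diff) / sd(diff).
    """
    a, b = np.asarray(pre, dtype=float), np.asarray(post, dtype=float)
    if a.size != b.size:
        raise ValidationError("paired samples must have equal length")
    n = a.size
    if n < 2:
        raise ValidationError("need n >= 2 pairs")
    diff = b - a
    sd = diff.std(ddof=1)
    df = float(n - 1)
    if sd == 0.0:
        if diff.mean() == 0.0:
            return StatsResult("paired_t", 0.0, df, 1.0, 0.0, "cohens_dz",
                               labels, (n, n))
        return StatsResult("paired_t", math.copysign(math.inf, diff.mean()), df, 0.0,
                           math.inf, "cohens_dz", labels, (n, n),
                           note="zero-variance differences with nonzero mean")
    t = diff.mean() / (sd / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    dz = diff.mean() / sd
    return StatsResult("paired_t", float(t), df, p, float(dz), "cohens_dz",
                       labels, (n, n))


def one_way_anova(groups) -> StatsResult:
    """One-way fixed-effects ANOVA: F(k−1, N−k) and η² = SS_between / SS_total."""
    labels, arrays = _as_arrays(groups)
    k = len(arrays)
    if k < 2:
        raise ValidationError("ANOVA needs >= 2 groups")
    for lab, a in zip(labels, arrays):
        if a.size < 2:
            raise ValidationError(f"group {lab!r} has n={a.size} < 2")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ss_total = ss_between + ss_within
    df1, df2 = float(k - 1), float(all_vals.size - k)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return StatsResult("one_way_anova", 0.0, (df1, df2), 1.0, 0.0, "eta_squared",
                               tuple(labels), tuple(a.size for a in arrays))
        return StatsResult("one_way_anova", math.inf, (df1, df2), 0.0, 1.0,
                           "eta_squared", tuple(labels), tuple(a.size for a in arrays),
                           note="zero within-group variance")
    f = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(f, df1, df2))
    eta2 = ss_between / ss_total if ss_total > 0 else 0.0
    return StatsResult("one_way_anova", float(f), (df1, df2), p, float(eta2),
                       "eta_squared", tuple(labels), tuple(a.size for a in arrays))


def posthoc_pairwise(
    groups: Mapping[str, Sequence[float]],
    correction: str = "none",
    *,
    variance_policy: str = "pooled",
) -> dict[tuple[str, str], StatsResult]:
    """Pairwise independent t-tests for all unordered group pairs.

    df per pair is n_i + n_j − 2 (pooled). ``correction='bonferroni'``
    multiplies each p by the number of pairs, capped at 1. The returned dict
    holds both key orders mapped to the same result, so result(i, j) ==
    result(j, i).
    """
    if correction not in ("none", "bonferroni"):
        raise ValidationError(f"unknown correction {correction!r}")
    labels = list(groups)
    if len(labels) < 2:
        raise ValidationError("need >= 2 groups for pairwise comparisons")
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
    out: dict[tuple[str, str], StatsResult] = {}
    m = len(pairs)
    for a, b in pairs:
        res = independent_t(groups[a], groups[b], variance_policy, labels=(a, b))
        if correction == "bonferroni":
            res = StatsResult(
                res.test, res.statistic, res.df, min(1.0, res.p * m),
                res.effect_size, res.effect_size_type, res.groups, res.n,
                note=(res.note + " bonferroni-adjusted").strip(),
            )
        out[(a, b)] = res
        out[(b, a)] = res
    return out
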