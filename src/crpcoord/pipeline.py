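"""End-to-end orchestration: trials → CRP → MARP/DP → group statistics → report.

The analysis follows the study design: a pre-training equivalence t-test
between the two novice groups, three-group ANOVAs with pairwise post hoc
t-tests (pre and post training), and within-group paired pre/post t-tests,
all on per-subject MARP and DP for each joint coupling, each with effect
sizes and an assumption report. Assumption-gate failures are logged as
warnings and the parametric analysis continues.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import pathlib
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__ as _version
from .errors import ValidationError
from .io import (
    AnalysisConfig,
    AngleTrial,
    CohortManifest,
    group_summary,
    read_manifest,
    read_trial_table,
    subject_metrics_frame,
    write_json,
)
from .metrics import CouplingMetrics, EnsembleCurve, ensemble_curve, subject_coupling_metrics
from .phase import compute_crp
from .stats import (
    AssumptionReport,
    StatsResult,
    assumption_gate,
    independent_t,
    one_way_anova,
    paired_t,
    posthoc_pairwise,
)

logger = logging.getLogger("crpcoord")

_INDICES = ("marp", "dp")


@dataclass
class ReportBundle:
    """Everything one run produces, traceable to input trials by provenance."""

    config: AnalysisConfig
    subject_metrics: pd.DataFrame  # one row per subject/stage/coupling
    summary: pd.DataFrame  # group mean (SD) table
    assumptions: dict  # (index, coupling) -> AssumptionReport
    pretest_t: pd.DataFrame  # novice pre-training equivalence t-tests
    pre_anova: pd.DataFrame
    pre_posthoc: pd.DataFrame
    paired: pd.DataFrame
    post_anova: pd.DataFrame
    post_posthoc: pd.DataFrame
    ensembles: dict  # (group, stage, coupling) -> EnsembleCurve
    metadata: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "subject_metrics": self.subject_metrics,
            "group_summary": self.summary,
            "pretest_t": self.pretest_t,
            "pre_anova": self.pre_anova,
            "pre_posthoc": self.pre_posthoc,
            "paired_t": self.paired,
            "post_anova": self.post_anova,
            "post_posthoc": self.post_posthoc,
        }

    def write(self, out_dir) -> None:
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables().items():
            df.to_csv(out / f"{name}.csv", index=False, float_format="%.10g")
        write_json(_assumptions_json(self.assumptions), out / "assumptions.json")
        write_json(self.metadata, out / "run_metadata.json")
        ens_dir = out / "ensembles"
        ens_dir.mkdir(exist_ok=True)
        for (group, stage, coupling), ens in self.ensembles.items():
            pd.DataFrame(
                {
                    "cycle_pct": ens.cycle_fraction,
                    "mean_theta": ens.mean_theta,
                    "sd_theta": ens.sd_theta,
                    "n": ens.n,
                }
            ).to_csv(
                ens_dir / f"{group}_{stage}_{coupling[0]}-{coupling[1]}.csv",
                index=False,
                float_format="%.10g",
            )


def _assumptions_json(assumptions: Mapping) -> dict:
    out = {}
    for (index, coupling), rep in assumptions.items():
        out[f"{index}/{coupling}"] = {
            "alpha": rep.alpha,
            "shapiro": {k: list(v) for k, v in rep.shapiro.items()},
            "levene": list(rep.levene) if rep.levene else None,
            "all_passed": rep.all_passed,
        }
    return out


def _coupling_label(coupling) -> str:
    return f"{coupling[0]}-{coupling[1]}"


def _df_str(df) -> str:
    if isinstance(df, tuple):
        return f"({df[0]:g},{df[1]:g})"
    return f"{df:g}"


def _result_row(res: StatsResult, **extra) -> dict:
    row = dict(extra)
    row.update(
        test=res.test,
        statistic=res.statistic,
        df=_df_str(res.df),
        p=res.p,
        effect_size=res.effect_size,
        effect_size_type=res.effect_size_type,
        groups="|".join(res.groups),
        n="|".join(str(x) for x in res.n),
        note=res.note,
    )
    return row


# ---------------------------------------------------------------------------
# Core analysis (in-memory)


def compute_subject_metrics(
    trials: Sequence[AngleTrial], config: AnalysisConfig
) -> list[CouplingMetrics]:
    """Per-subject/stage/coupling MARP and DP from raw trials."""
    by_cell: dict[tuple[str, str, str], list[AngleTrial]] = {}
    for t in trials:
        by_cell.setdefault((t.subject_id, t.group, t.stage), []).append(t)
    metrics = []
    for key in sorted(by_cell):
        cell_trials = sorted(by_cell[key], key=lambda t: t.trial_index)
        for coupling in config.couplings:
            metrics.append(subject_coupling_metrics(cell_trials, coupling, config))
    return metrics


def compute_ensembles(
    trials: Sequence[AngleTrial], config: AnalysisConfig
) -> dict[tuple[str, str, tuple], EnsembleCurve]:
    """Intergroup ensemble mean ± SD CRP per (group, stage, coupling)."""
    by_cell: dict[tuple[str, str], list[AngleTrial]] = {}
    for t in trials:
        by_cell.setdefault((t.group, t.stage), []).append(t)
    out = {}
    for (group, stage), cell_trials in sorted(by_cell.items()):
        for coupling in config.couplings:
            curves = [compute_crp(t, coupling, config.n_cycle_points) for t in cell_trials]
            if len(curves) >= 2:
                out[(group, stage, coupling)] = ensemble_curve(curves)
    return out


def _metric_values(rows: pd.DataFrame, group: str, stage: str, coupling_label: str,
                   index: str) -> np.ndarray:
    sel = rows[
        (rows["group"] == group)
        & (rows["stage"] == stage)
        & (rows["coupling"] == coupling_label)
    ].sort_values("subject_id")
    vals = sel[index].to_numpy(dtype=float)
    return vals[np.isfinite(vals)]


def analyze_cohort(
    trials: Sequence[AngleTrial],
    manifest: CohortManifest | None,
    config: AnalysisConfig | None = None,
) -> ReportBundle:
    """Run the full coordination analysis on in-memory trials."""
    config = config or AnalysisConfig()
    t0 = time.perf_counter()
    metrics = compute_subject_metrics(trials, config)
    rows = subject_metrics_frame(metrics)
    summary = group_summary(rows)
    logger.info(
        "metrics: %d trials -> %d subject-level rows (%.2fs)",
        len(trials), len(rows), time.perf_counter() - t0,
    )

    assumptions: dict = {}
    pretest, pre_anova_rows, pre_post_rows = [], [], []
    paired_rows, post_anova_rows, post_post_rows = [], [], []
    stages_present = set(zip(rows["group"], rows["stage"]))

    for coupling in config.couplings:
        lab = _coupling_label(coupling)
        for index in _INDICES:
            pre_groups = {}
            for group, stage in (("control", "pre"), ("test", "pre"), ("target", "single")):
                if (group, stage) in stages_present:
                    vals = _metric_values(rows, group, stage, lab, index)
                    if vals.size:
                        pre_groups[group] = vals
            if len(pre_groups) >= 2 and all(v.size >= 3 for v in pre_groups.values()):
                rep = assumption_gate(pre_groups, config.alpha)
                assumptions[(index, lab)] = rep
                if not rep.all_passed:
                    logger.warning(
                        "assumption gate failed for %s/%s; parametric analysis continues",
                        index, lab,
                    )
            # novice pre-training equivalence
            if {"control", "test"} <= set(pre_groups):
                res = independent_t(
                    pre_groups["control"], pre_groups["test"],
                    config.variance_policy, alpha=config.alpha,
                    labels=("control", "test"),
                )
                pretest.append(_result_row(res, index=index, coupling=lab))
            # pre-training three-group ANOVA + post hoc
            if len(pre_groups) >= 2:
                res = one_way_anova(pre_groups)
                pre_anova_rows.append(_result_row(res, index=index, coupling=lab))
                ph = posthoc_pairwise(
                    pre_groups, config.posthoc_correction,
                    variance_policy=config.variance_policy,
                )
                for (a, b), r in sorted(ph.items()):
                    if a < b:
                        pre_post_rows.append(
                            _result_row(r, index=index, coupling=lab, group1=a, group2=b)
                        )
            # paired pre/post per novice group
            for group in ("control", "test"):
                if (group, "pre") in stages_present and (group, "post") in stages_present:
                    pre_df = rows[
                        (rows["group"] == group) & (rows["stage"] == "pre")
                        & (rows["coupling"] == lab)
                    ].set_index("subject_id")[index]
                    post_df = rows[
                        (rows["group"] == group) & (rows["stage"] == "post")
                        & (rows["coupling"] == lab)
                    ].set_index("subject_id")[index]
                    common = sorted(set(pre_df.index) & set(post_df.index))
                    pre_v = pre_df.loc[common].to_numpy(dtype=float)
                    post_v = post_df.loc[common].to_numpy(dtype=float)
                    ok = np.isfinite(pre_v) & np.isfinite(post_v)
                    if ok.sum() >= 2:
                        res = paired_t(pre_v[ok], post_v[ok], labels=("pre", "post"))
                        paired_rows.append(
                            _result_row(res, group=group, index=index, coupling=lab)
                        )
            # post-training three-group ANOVA + post hoc
            post_groups = {}
            for group, stage in (("control", "post"), ("test", "post"), ("target", "single")):
                if (group, stage) in stages_present:
                    vals = _metric_values(rows, group, stage, lab, index)
                    if vals.size:
                        post_groups[group] = vals
            if len(post_groups) >= 2:
                res = one_way_anova(post_groups)
                post_anova_rows.append(_result_row(res, index=index, coupling=lab))
                ph = posthoc_pairwise(
                    post_groups, config.posthoc_correction,
                    variance_policy=config.variance_policy,
                )
                for (a, b), r in sorted(ph.items()):
                    if a < b:
                        post_post_rows.append(
                            _result_row(r, index=index, coupling=lab, group1=a, group2=b)
                        )
    logger.info("statistics: %d pretest, %d ANOVA, %d paired tests",
                len(pretest), len(pre_anova_rows) + len(post_anova_rows), len(paired_rows))

    ensembles = compute_ensembles(trials, config)

    cfg_dict = config.to_dict()
    metadata = {
        "version": _version,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest()[:16],
        "seed": config.seed,
        "n_trials": len(trials),
        "n_subjects": manifest.group_counts() if manifest is not None else None,
    }
    return ReportBundle(
        config=config,
        subject_metrics=rows,
        summary=summary,
        assumptions=assumptions,
        pretest_t=pd.DataFrame(pretest),
        pre_anova=pd.DataFrame(pre_anova_rows),
        pre_posthoc=pd.DataFrame(pre_post_rows),
        paired=pd.DataFrame(paired_rows),
        post_anova=pd.DataFrame(post_anova_rows),
        post_posthoc=pd.DataFrame(post_post_rows),
        ensembles=ensembles,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# File-based entry point


def load_trials(manifest: CohortManifest, base_dir) -> list[AngleTrial]:
    """Read every trial file listed in the manifest, relative to base_dir."""
    base = pathlib.Path(base_dir)
    trials = []
    counters: dict[tuple[str, str], int] = {}
    for _, row in manifest.records.iterrows():
        key = (row["subject_id"], row["stage"])
        counters[key] = counters.get(key, 0) + 1
        path = base / row["trial_path"]
        if not path.exists():
            raise ValidationError(f"trial file not found: {path}")
        trials.append(
            read_trial_table(
                path,
                subject_id=row["subject_id"],
                group=row["group"],
                stage=row["stage"],
                trial_index=counters[key],
            )
        )
    return trials


def run_analysis(
    config: AnalysisConfig,
    manifest_path,
    out_dir,
    *,
    make_figures: bool = True,
) -> ReportBundle:
    """Read a cohort from disk, analyze it, and write the report bundle."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    try:
        manifest_path = pathlib.Path(manifest_path)
        manifest = read_manifest(manifest_path)
        logger.info("manifest: %s subjects per group", manifest.group_counts())
        trials = load_trials(manifest, manifest_path.parent)
        logger.info("loaded %d trials", len(trials))
        bundle = analyze_cohort(trials, manifest, config)
        bundle.write(out)
        if make_figures:
            fig_dir = out / "figures"
            plot_metric_bars(bundle.summary, fig_dir)
            for (group, stage, coupling), ens in bundle.ensembles.items():
                plot_ensemble(
                    ens,
                    fig_dir / f"ensemble_{group}_{stage}_{_coupling_label(coupling)}.png",
                )
        logger.info("report written to %s", out)
        return bundle
    finally:
        logger.removeHandler(handler)
        handler.close()


# ---------------------------------------------------------------------------
# Figures


def plot_metric_bars(summary: pd.DataFrame, out_dir) -> list[pathlib.Path]:
    """Bar chart per (index, coupling): group/stage means with SD error bars."""
    if summary.empty:
        raise ValidationError("no metrics to plot")
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for index in _INDICES:
        for lab in sorted(summary["coupling"].unique()):
            sel = summary[summary["coupling"] == lab]
            labels = [f"{g}\n{s}" for g, s in zip(sel["group"], sel["stage"])]
            means = sel[f"{index}_mean"].to_numpy(dtype=float)
            sds = np.nan_to_num(sel[f"{index}_sd"].to_numpy(dtype=float))
            fig, ax = plt.subplots(figsize=(5, 3.4))
            ax.bar(labels, means, yerr=sds, capsize=4, color="steelblue")
            ax.set_ylabel(f"{index.upper()} (deg)")
            ax.set_title(f"{index.upper()} {lab}")
            fig.tight_layout()
            path = out / f"{index}_{lab}.png"
            fig.savefig(path, dpi=100)
            plt.close(fig)
            paths.append(path)
    return paths


def plot_ensemble(ens: EnsembleCurve, path) -> pathlib.Path:
    """Ensemble CRP: mean line with a ±SD dashed envelope over the cycle."""
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(5, 3.4))
    ax.plot(ens.cycle_fraction, ens.mean_theta, color="tab:blue", label="mean")
    ax.plot(ens.cycle_fraction, ens.mean_theta + ens.sd_theta, "r--", lw=0.9, label="±SD")
    ax.plot(ens.cycle_fraction, ens.mean_theta - ens.sd_theta, "r--", lw=0.9)
    ax.set_xlabel("movement cycle (%)")
    ax.set_ylabel("relative phase (deg)")
    ax.set_title(f"CRP {_coupling_label(ens.coupling)} (n={ens.n})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
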