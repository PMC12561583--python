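"""Reading and writing of trial tables, cohort manifests, metric tables and configs.

On-disk dialect: comma-delimited UTF-8 with a header row. Trial tables carry a
``time_s`` column plus one column per joint, angles in degrees (a ``_rad``
suffix on a joint column marks radians and is converted on read). Manifests
carry one row per (subject, stage, trial file) with demographics.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, SchemaError, ValidationError

GROUPS = ("control", "test", "target")
STAGES = ("pre", "post", "single")
REQUIRED_JOINTS = ("ankle", "knee", "pelvis")

TIME_COLUMN = "time_s"

#: column suffixes understood as unit markers on joint columns
_UNIT_SUFFIX = re.compile(r"^(?P<joint>.+?)_(?P<unit>deg|rad)$")


# ---------------------------------------------------------------------------
# AngleTrial


@dataclass(frozen=True)
class AngleTrial:
    """One trial's sampled sagittal-plane joint-angle series.

    Angles are stored in degrees relative to each joint's neutral position;
    no anatomical sign convention is imposed.
    """

    subject_id: str
    group: str
    stage: str
    trial_index: int
    sample_rate: float
    time: np.ndarray
    angles: Mapping[str, np.ndarray]

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.trial_index < 1:
            raise ValidationError("trial_index must be a positive integer")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be > 0")
        t = np.asarray(self.time, dtype=float)
        object.__setattr__(self, "time", t)
        if t.size < 8:
            raise ValidationError(f"trial too short: {t.size} samples (need >= 8)")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValidationError("time must be strictly increasing")
        if not np.allclose(dt, dt.mean(), rtol=1e-6, atol=0.0):
            raise ValidationError("sample spacing must be uniform (rtol 1e-6)")
        angles = {k: np.asarray(v, dtype=float) for k, v in self.angles.items()}
        object.__setattr__(self, "angles", angles)
        for joint, series in angles.items():
            if series.shape != t.shape:
                raise ValidationError(
                    f"angle series {joint!r} has length {series.size}, expected {t.size}"
                )
            if not np.all(np.isfinite(series)):
                bad = np.flatnonzero(~np.isfinite(series)).tolist()
                raise ValidationError(f"non-finite angles in {joint!r} at rows {bad}")

    @property
    def dt(self) -> float:
        return float(np.mean(np.diff(self.time)))

    @property
    def n_samples(self) -> int:
        return int(self.time.size)


def read_trial_table(
    path,
    *,
    subject_id: str,
    group: str,
    stage: str,
    trial_index: int = 1,
    required_joints: Sequence[str] = REQUIRED_JOINTS,
) -> AngleTrial:
    """Read one trial CSV (``time_s`` + one column per joint) into an AngleTrial.

    Joint columns may carry a ``_deg`` or ``_rad`` unit suffix; unsuffixed
    columns are taken as degrees. Radian columns are converted to degrees.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if TIME_COLUMN not in df.columns:
        raise SchemaError(f"{path}: missing required time column {TIME_COLUMN!r}")
    angles: dict[str, np.ndarray] = {}
    for col in df.columns:
        if col == TIME_COLUMN:
            continue
        m = _UNIT_SUFFIX.match(col)
        joint, unit = (m.group("joint"), m.group("unit")) if m else (col, "deg")
        series = df[col].to_numpy(dtype=float)
        if np.any(pd.isna(df[col])):
            bad = np.flatnonzero(pd.isna(df[col]).to_numpy()).tolist()
            raise ValidationError(f"{path}: NaN cells in column {col!r} at rows {bad}")
        if unit == "rad":
            series = np.degrees(series)
        angles[joint] = series
    for joint in required_joints:
        if joint not in angles:
            raise SchemaError(f"{path}: missing required joint column {joint!r}")
    time = df[TIME_COLUMN].to_numpy(dtype=float)
    if np.any(pd.isna(df[TIME_COLUMN])):
        bad = np.flatnonzero(pd.isna(df[TIME_COLUMN]).to_numpy()).tolist()
        raise ValidationError(f"{path}: NaN cells in column {TIME_COLUMN!r} at rows {bad}")
    dt = np.diff(time)
    if np.any(dt <= 0):
        raise ValidationError(f"{path}: time column must be strictly increasing")
    sample_rate = 1.0 / float(np.mean(dt))
    return AngleTrial(
        subject_id=subject_id,
        group=group,
        stage=stage,
        trial_index=trial_index,
        sample_rate=sample_rate,
        time=time,
        angles=angles,
    )


def write_trial_table(trial: AngleTrial, path) -> None:
    """Write an AngleTrial as CSV with full float precision (round-trip safe)."""
    data = {TIME_COLUMN: trial.time}
    data.update({joint: series for joint, series in trial.angles.items()})
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# CohortManifest

MANIFEST_COLUMNS = ("subject_id", "group", "stage", "trial_path", "age_y", "height_m", "weight_kg")


@dataclass
class CohortManifest:
    """Trial-to-subject assignment with demographics; one row per trial file."""

    records: pd.DataFrame

    def __post_init__(self):
        df = self.records
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"manifest missing columns {missing}")
        bad_group = set(df["group"]) - set(GROUPS)
        if bad_group:
            raise ValidationError(f"unknown group labels {sorted(bad_group)}")
        bad_stage = set(df["stage"]) - set(STAGES)
        if bad_stage:
            raise ValidationError(f"unknown stage labels {sorted(bad_stage)}")
        tgt = df[df["group"] == "target"]
        if not (tgt["stage"] == "single").all():
            raise ValidationError("target-group records must have stage 'single'")
        dup = df.duplicated(subset=["subject_id", "stage", "trial_path"])
        if dup.any():
            raise ValidationError(
                f"duplicate (subject, stage, trial) rows at indices {np.flatnonzero(dup).tolist()}"
            )
        # BMI = weight / height^2 (kg / m^2), computed on load
        df = df.copy()
        df["bmi"] = df["weight_kg"] / df["height_m"] ** 2
        self.records = df

    def group_counts(self) -> dict[str, int]:
        """Number of distinct subjects per group."""
        return {
            g: int(self.records.loc[self.records["group"] == g, "subject_id"].nunique())
            for g in GROUPS
            if (self.records["group"] == g).any()
        }

    def subjects(self) -> pd.DataFrame:
        """One row per (subject, group) with demographics."""
        return (
            self.records.groupby(["subject_id", "group"], as_index=False)
            .agg(age_y=("age_y", "first"), height_m=("height_m", "first"),
                 weight_kg=("weight_kg", "first"), bmi=("bmi", "first"))
            .sort_values(["group", "subject_id"], ignore_index=True)
        )


def read_manifest(path) -> CohortManifest:
    df = pd.read_csv(path, float_precision="round_trip")
    return CohortManifest(df)


def write_manifest(manifest: CohortManifest, path) -> None:
    manifest.records.drop(columns=["bmi"]).to_csv(path, index=False, float_format="%.17g")


def bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index, weight / height² (kg/m²)."""
    return weight_kg / height_m**2


# ---------------------------------------------------------------------------
# AnalysisConfig

Coupling = tuple[str, str]

DEFAULT_COUPLINGS: tuple[Coupling, ...] = (("ankle", "knee"), ("knee", "pelvis"))


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the coordination analysis.

    couplings
        (distal, proximal) joint pairs; ankle is distal to knee, knee to pelvis.
    n_cycle_points
        size of the 0–100% cycle grid the CRP curves are resampled onto.
    """

    couplings: tuple[Coupling, ...] = DEFAULT_COUPLINGS
    n_cycle_points: int = 101
    angle_unit_out: str = "degrees"
    alpha: float = 0.05
    posthoc_correction: str = "none"
    variance_policy: str = "pooled"
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(
            self, "couplings", tuple((str(d), str(p)) for d, p in self.couplings)
        )
        if not self.couplings:
            raise ConfigError("couplings must be non-empty")
        if self.n_cycle_points < 11:
            raise ConfigError(f"n_cycle_points must be >= 11, got {self.n_cycle_points}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.angle_unit_out not in ("degrees", "radians"):
            raise ConfigError(f"angle_unit_out must be degrees|radians, got {self.angle_unit_out}")
        if self.posthoc_correction not in ("none", "bonferroni"):
            raise ConfigError(f"posthoc_correction must be none|bonferroni")
        if self.variance_policy not in ("pooled", "welch", "auto_levene"):
            raise ConfigError(f"variance_policy must be pooled|welch|auto_levene")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["couplings"] = [list(c) for c in self.couplings]
        return d


def load_config(path) -> AnalysisConfig:
    """Load an AnalysisConfig from YAML (.yml/.yaml) or TOML (.toml)."""
    path = pathlib.Path(path)
    if path.suffix in (".yml", ".yaml"):
        raw = yaml.safe_load(path.read_text()) or {}
    elif path.suffix == ".toml":
        import tomllib

        raw = tomllib.loads(path.read_text())
    else:
        raise ConfigError(f"unsupported config format {path.suffix!r} (use YAML or TOML)")
    if "couplings" in raw:
        raw["couplings"] = tuple(tuple(c) for c in raw["couplings"])
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys {sorted(unknown)}")
    return AnalysisConfig(**raw)


# ---------------------------------------------------------------------------
# Metric tables


def write_metrics_table(metrics, path) -> pd.DataFrame:
    """Write the group-summary table: one row per (group, stage, coupling).

    ``metrics`` is a collection of per-subject CouplingMetrics. Mean and SD
    columns are plain numeric; SD is NaN where only one subject contributes.
    Row order is deterministic (group, stage, coupling).
    """
    rows = subject_metrics_frame(metrics)
    if rows.empty:
        raise ValidationError("cannot write a metrics table from an empty collection")
    summary = group_summary(rows)
    summary.to_csv(path, index=False, float_format="%.10g")
    return summary


def subject_metrics_frame(metrics) -> pd.DataFrame:
    """Per-subject metrics as a tidy DataFrame (one row per CouplingMetrics)."""
    rows = [
        {
            "subject_id": m.subject_id,
            "group": m.group,
            "stage": m.stage,
            "coupling": f"{m.coupling[0]}-{m.coupling[1]}",
            "marp": m.marp,
            "dp": m.dp,
            "n_cycles": m.n_cycles,
        }
        for m in metrics
    ]
    return pd.DataFrame(rows)


def group_summary(subject_rows: pd.DataFrame) -> pd.DataFrame:
    """Group mean (SD) of per-subject MARP and DP per (group, stage, coupling)."""
    grouped = subject_rows.groupby(["group", "stage", "coupling"], as_index=False)
    summary = grouped.agg(
        n=("subject_id", "nunique"),
        marp_mean=("marp", "mean"),
        marp_sd=("marp", lambda s: s.std(ddof=1)),
        dp_mean=("dp", "mean"),
        dp_sd=("dp", lambda s: s.std(ddof=1)),
    )
    return summary.sort_values(["group", "stage", "coupling"], ignore_index=True)


def write_json(obj, path) -> None:
    pathlib.Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))
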