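"""Domain types and CSV round-trip for posturographic trial data and results.

The data model mirrors a standard quiet-stance posturography session: a
stabilometric force platform samples center-of-pressure (CoP) displacement in
the mediolateral (ML) and anterior-posterior (AP) directions at 100 Hz for
30 s (3000 samples per axis), and a waist-worn inertial measurement unit (IMU)
records nine trunk-kinematics channels at the same rate: triaxial angular
acceleration (deg/s^2), triaxial angular velocity (deg/s) and the roll/pitch/
yaw orientation angles (deg).

CSV layout is an artifact convention: comma-separated, '.' decimal, UTF-8,
with '#'-prefixed metadata lines (subject, group, condition, fs) before the
header row. Timestamps are informative only; sampling is assumed uniform.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GROUPS = ("addicted", "non_addicted")
#: Stance conditions: bipedal / single-leg (R/L), eyes open (eo) / closed (ec).
CONDITIONS = ("2eo", "2ec", "eoR", "eoL", "ecR", "ecL")
#: IMU channel order: angular acceleration, angular velocity, orientation.
IMU_CHANNELS = (
    "acc_x", "acc_y", "acc_z",
    "gyro_x", "gyro_y", "gyro_z",
    "roll", "pitch", "yaw",
)

DEFAULT_FS = 100.0      # Hz
DEFAULT_DURATION = 30.0  # s -> 3000 samples at 100 Hz


class SwayLabError(Exception):
    """Base class for all package errors."""


class FormatError(SwayLabError):
    """A file does not conform to the expected CSV schema."""


class ValidationError(SwayLabError):
    """Data are schema-conformant but violate an invariant (NaN/Inf, length)."""


class ParameterError(SwayLabError):
    """An estimator or generator parameter is out of its admissible range."""


class DegenerateInputError(SwayLabError):
    """Input is valid but degenerate for the requested computation."""


class EstimationError(SwayLabError):
    """An estimator could not produce a result (e.g. no admissible neighbor)."""


def _check_finite(name: str, values: np.ndarray) -> None:
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        raise ValidationError(
            f"{name} contains a non-finite value at row index {int(bad[0])}"
        )


def _check_group(group: str) -> None:
    if group not in GROUPS:
        raise ValidationError(f"unknown group {group!r}; expected one of {GROUPS}")


def _check_condition(condition: str) -> None:
    if condition not in CONDITIONS:
        raise ValidationError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}"
        )


@dataclass
class CoPTrial:
    """One condition's CoP displacement series (mm) on both sway axes."""

    subject_id: str
    group: str
    condition: str
    ml: np.ndarray
    ap: np.ndarray
    fs: float = DEFAULT_FS

    def __post_init__(self) -> None:
        _check_group(self.group)
        _check_condition(self.condition)
        self.ml = np.asarray(self.ml, dtype=float)
        self.ap = np.asarray(self.ap, dtype=float)
        if self.ml.ndim != 1 or self.ap.ndim != 1:
            raise ValidationError("ml and ap must be one-dimensional series")
        if len(self.ml) != len(self.ap):
            raise ValidationError(
                f"axis length mismatch: len(ml)={len(self.ml)} != len(ap)={len(self.ap)}"
            )
        if not self.fs > 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        _check_finite("ml", self.ml)
        _check_finite("ap", self.ap)

    @property
    def n_samples(self) -> int:
        return len(self.ml)


@dataclass
class IMUTrial:
    """One condition's nine-channel IMU series (deg/s^2, deg/s, deg)."""

    subject_id: str
    group: str
    condition: str
    channels: dict[str, np.ndarray]
    fs: float = DEFAULT_FS

    def __post_init__(self) -> None:
        _check_group(self.group)
        _check_condition(self.condition)
        missing = [c for c in IMU_CHANNELS if c not in self.channels]
        extra = [c for c in self.channels if c not in IMU_CHANNELS]
        if missing or extra:
            raise ValidationError(
                f"IMU channel set mismatch: missing={missing}, extra={extra}"
            )
        self.channels = {
            name: np.asarray(self.channels[name], dtype=float) for name in IMU_CHANNELS
        }
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValidationError(f"IMU channels have unequal lengths: {sorted(lengths)}")
        if not self.fs > 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        for name, values in self.channels.items():
            _check_finite(name, values)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))


@dataclass
class SwayMetrics:
    """The ten per-trial sway outcomes: 4 linear + SampEn/FD/LyE per axis.

    ``flags`` collects soft warnings (e.g. an FD estimate outside [1, 2])
    without failing the trial.
    """

    cop_total: float
    cop_ml: float
    cop_ap: float
    ellipse: float
    sampen_ml: float
    sampen_ap: float
    fd_ml: float
    fd_ap: float
    lye_ml: float
    lye_ap: float
    flags: list[str] = field(default_factory=list)

    _FIELDS = (
        "cop_total", "cop_ml", "cop_ap", "ellipse",
        "sampen_ml", "sampen_ap", "fd_ml", "fd_ap", "lye_ml", "lye_ap",
    )

    def __post_init__(self) -> None:
        for name in ("cop_total", "cop_ml", "cop_ap", "ellipse"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        for name in ("fd_ml", "fd_ap"):
            fd = getattr(self, name)
            if math.isfinite(fd) and not 1.0 <= fd <= 2.0:
                self.flags.append(f"{name}={fd:.3f} outside [1, 2]")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self._FIELDS}


@dataclass
class GroupComparison:
    """One variable x condition row of a two-group nonparametric comparison."""

    variable: str
    condition: str
    median_q1_q3_a: tuple[float, float, float]
    median_q1_q3_b: tuple[float, float, float]
    U: float
    Z: float
    p: float
    r: float
    effect_class: str
    significant: bool

    def __post_init__(self) -> None:
        _check_condition(self.condition)
        if not 0.0 <= self.p <= 1.0:
            raise ValidationError(f"p={self.p} outside [0, 1]")
        if self.Z != 0.0 and self.r != 0.0 and math.copysign(1, self.Z) != math.copysign(1, self.r):
            raise ValidationError("sign(r) must equal sign(Z)")


@dataclass
class CorrelationHit:
    """One significant sway-metric vs IMU-channel correlation."""

    group: str
    condition: str
    metric_name: str
    imu_channel: str
    rho: float
    p: float
    strength: str

    def __post_init__(self) -> None:
        _check_group(self.group)
        _check_condition(self.condition)
        if not -1.0 <= self.rho <= 1.0:
            raise ValidationError(f"rho={self.rho} outside [-1, 1]")
        if not 0.0 <= self.p <= 1.0:
            raise ValidationError(f"p={self.p} outside [0, 1]")


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def _read_with_metadata(path: Path) -> tuple[dict[str, str], pd.DataFrame]:
    meta: dict[str, str] = {}
    skip = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    df = pd.read_csv(path, skiprows=skip)
    return meta, df


def _meta_header(meta: dict[str, object]) -> str:
    return "".join(f"# {k} = {v}\n" for k, v in meta.items())


def read_cop_csv(
    path: str | Path,
    *,
    subject_id: str | None = None,
    group: str | None = None,
    condition: str | None = None,
    fs: float | None = None,
) -> CoPTrial:
    """Read a CoP trial from CSV (columns time_s, ml_mm, ap_mm).

    Metadata come from '#'-prefixed ``key = value`` lines or the keyword
    overrides. The time column is informative only.
    """
    path = Path(path)
    meta, df = _read_with_metadata(path)
    for col in ("ml_mm", "ap_mm"):
        if col not in df.columns:
            raise FormatError(f"{path}: required column {col!r} is missing")
    return CoPTrial(
        subject_id=subject_id or meta.get("subject", path.stem),
        group=group or meta.get("group", ""),
        condition=condition or meta.get("condition", ""),
        ml=df["ml_mm"].to_numpy(float),
        ap=df["ap_mm"].to_numpy(float),
        fs=float(fs if fs is not None else meta.get("fs", DEFAULT_FS)),
    )


def write_cop_csv(trial: CoPTrial, path: str | Path) -> Path:
    path = Path(path)
    t = np.arange(trial.n_samples) / trial.fs
    df = pd.DataFrame({"time_s": t, "ml_mm": trial.ml, "ap_mm": trial.ap})
    meta = {
        "subject": trial.subject_id,
        "group": trial.group,
        "condition": trial.condition,
        "fs": trial.fs,
    }
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_header(meta))
        df.to_csv(fh, index=False, lineterminator="\n")
    return path


def read_imu_csv(
    path: str | Path,
    *,
    subject_id: str | None = None,
    group: str | None = None,
    condition: str | None = None,
    fs: float | None = None,
) -> IMUTrial:
    """Read an IMU trial from CSV with the nine named channel columns."""
    path = Path(path)
    meta, df = _read_with_metadata(path)
    missing = [c for c in IMU_CHANNELS if c not in df.columns]
    extra = [c for c in df.columns if c not in IMU_CHANNELS and c != "time_s"]
    if missing or extra:
        raise FormatError(
            f"{path}: IMU channel columns mismatch: missing={missing}, extra={extra}"
        )
    return IMUTrial(
        subject_id=subject_id or meta.get("subject", path.stem),
        group=group or meta.get("group", ""),
        condition=condition or meta.get("condition", ""),
        channels={c: df[c].to_numpy(float) for c in IMU_CHANNELS},
        fs=float(fs if fs is not None else meta.get("fs", DEFAULT_FS)),
    )


def write_imu_csv(trial: IMUTrial, path: str | Path) -> Path:
    path = Path(path)
    t = np.arange(trial.n_samples) / trial.fs
    data = {"time_s": t}
    data.update({c: trial.channels[c] for c in IMU_CHANNELS})
    meta = {
        "subject": trial.subject_id,
        "group": trial.group,
        "condition": trial.condition,
        "fs": trial.fs,
    }
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_header(meta))
        pd.DataFrame(data).to_csv(fh, index=False, lineterminator="\n")
    return path


_COMPARISON_COLUMNS = (
    "variable", "condition",
    "median_a", "q1_a", "q3_a", "median_b", "q1_b", "q3_b",
    "U", "Z", "p", "r", "effect_class", "significant",
)
_HIT_COLUMNS = ("group", "condition", "metric_name", "imu_channel", "rho", "p", "strength")


def _comparison_row(row: GroupComparison) -> dict[str, object]:
    d = {
        "variable": row.variable,
        "condition": row.condition,
        "median_a": row.median_q1_q3_a[0],
        "q1_a": row.median_q1_q3_a[1],
        "q3_a": row.median_q1_q3_a[2],
        "median_b": row.median_q1_q3_b[0],
        "q1_b": row.median_q1_q3_b[1],
        "q3_b": row.median_q1_q3_b[2],
        "U": row.U, "Z": row.Z, "p": row.p, "r": row.r,
        "effect_class": row.effect_class, "significant": row.significant,
    }
    return d


def write_results_csv(
    rows: Sequence[GroupComparison] | Sequence[CorrelationHit],
    path: str | Path,
    *,
    row_type: type | None = None,
) -> Path:
    """Write a homogeneous list of result records as a tidy CSV.

    An empty list writes a header-only file; pass ``row_type`` to choose the
    schema in that case (defaults to GroupComparison).
    """
    path = Path(path)
    types = {type(r) for r in rows}
    if len(types) > 1:
        raise TypeError(f"mixed result row types: {sorted(t.__name__ for t in types)}")
    rt = row_type or (types.pop() if types else GroupComparison)
    if rt is GroupComparison:
        records = [_comparison_row(r) for r in rows]  # type: ignore[arg-type]
        columns = _COMPARISON_COLUMNS
    elif rt is CorrelationHit:
        records = [dataclasses.asdict(r) for r in rows]  # type: ignore[arg-type]
        columns = _HIT_COLUMNS
    else:
        raise TypeError(f"unsupported result row type: {rt!r}")
    pd.DataFrame.from_records(records, columns=columns).to_csv(path, index=False)
    return path


def read_results_csv(path: str | Path) -> list[GroupComparison] | list[CorrelationHit]:
    """Read back a results CSV written by :func:`write_results_csv`."""
    df = pd.read_csv(path)
    if set(df.columns) == set(_COMPARISON_COLUMNS):
        return [
            GroupComparison(
                variable=str(r.variable), condition=str(r.condition),
                median_q1_q3_a=(r.median_a, r.q1_a, r.q3_a),
                median_q1_q3_b=(r.median_b, r.q1_b, r.q3_b),
                U=float(r.U), Z=float(r.Z), p=float(r.p), r=float(r.r),
                effect_class=str(r.effect_class), significant=bool(r.significant),
            )
            for r in df.itertuples()
        ]
    if set(df.columns) == set(_HIT_COLUMNS):
        return [
            CorrelationHit(
                group=str(r.group), condition=str(r.condition),
                metric_name=str(r.metric_name), imu_channel=str(r.imu_channel),
                rho=float(r.rho), p=float(r.p), strength=str(r.strength),
            )
            for r in df.itertuples()
        ]
    raise FormatError(f"{path}: unrecognized results schema: {list(df.columns)}")
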