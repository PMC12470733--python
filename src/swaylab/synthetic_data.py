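"""Synthetic two-group posturography cohorts for download-free testing.

The generator emulates the statistical structure the downstream analysis
assumes, not the biomechanics of stance:

* CoP axes are independent fractional-Brownian-motion (fBm) paths — quiet
  stance CoP is well described as persistent 1/f-like motion, and fBm has a
  known Higuchi fractal dimension FD = 2 - H, giving a closed-form oracle.
  Paths are low-pass filtered into a physiological band and linearly
  rescaled so the *expected* per-axis path length equals a condition x
  group target. Default targets are the published reference medians of a
  47-inmate cohort (19 with a documented substance-dependence history, 28
  without) across the six stance conditions, so generated cohorts echo the
  observed group contrasts (larger sway with dependence history, most
  pronounced in eyes-closed single-leg stance).
* IMU channels are a constant subject level plus smooth AR(1) noise; the
  subject levels concentrate on per-channel, per-condition baselines with
  additive group offsets taken from the same reference cohort's IMU
  median grid.
* Every generator is a pure function of its parameters and seed. Per-trial
  seeds derive from the master seed via numpy SeedSequence over the key
  (master_seed, subject_index, condition_index, stream).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sp_signal

from .io_model import (
    CONDITIONS,
    DEFAULT_DURATION,
    DEFAULT_FS,
    GROUPS,
    IMU_CHANNELS,
    CoPTrial,
    IMUTrial,
    ParameterError,
    ValidationError,
    read_cop_csv,
    read_imu_csv,
    write_cop_csv,
    write_imu_csv,
)

# ---------------------------------------------------------------------------
# Reference calibration grids (per-condition medians of the published
# 19 vs 28 reference cohort; path lengths in mm, IMU channels in native units)
# ---------------------------------------------------------------------------

#: condition -> group -> (ML path target, AP path target) [mm]
DEFAULT_PATH_TARGETS: dict[str, dict[str, tuple[float, float]]] = {
    "2eo": {"non_addicted": (130.5, 190.0), "addicted": (108.0, 187.0)},
    "2ec": {"non_addicted": (138.0, 314.5), "addicted": (161.0, 399.0)},
    "eoR": {"non_addicted": (718.0, 714.5), "addicted": (925.0, 828.0)},
    "eoL": {"non_addicted": (605.0, 632.5), "addicted": (774.0, 763.0)},
    "ecR": {"non_addicted": (2090.0, 1829.0), "addicted": (3089.0, 2463.0)},
    "ecL": {"non_addicted": (2013.5, 1822.5), "addicted": (2516.0, 2374.0)},
}

#: condition -> channel -> (baseline median, Q1, Q3, addicted median)
#: baseline/quartiles describe the non-dependent group.
DEFAULT_IMU_REFERENCE: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "2eo": {
        "acc_x": (9.7, 9.64, 9.76, 9.65),
        "acc_y": (-0.02, -0.32, 0.26, -0.38),
        "acc_z": (-0.24, -0.87, 0.77, 1.2),
        "gyro_x": (0.0, 0.0, 0.0, 0.0),
        "gyro_y": (0.0, 0.0, 0.0, 0.0),
        "gyro_z": (0.0, 0.0, 0.0, 0.0),
        "roll": (2.6, -84.1, 57.18, -34.2),
        "pitch": (-82.28, -85.05, -79.13, -79.3),
        "yaw": (-37.73, -98.93, 30.0, 15.12),
    },
    "2ec": {
        "acc_x": (9.69, 9.61, 9.78, 9.66),
        "acc_y": (-0.01, -0.58, 0.67, -0.22),
        "acc_z": (0.23, -1.49, 1.26, 0.3),
        "gyro_x": (0.0, 0.0, 0.0, 0.0),
        "gyro_y": (0.0, -0.06, 0.0, -0.03),
        "gyro_z": (0.0, 0.0, 0.0, 0.0),
        "roll": (-0.3, -128.6, 49.8, -34.68),
        "pitch": (-82.6, -84.6, -77.5, -80.48),
        "yaw": (-35.7, -127.3, 119.4, 21.61),
    },
    "eoR": {
        "acc_x": (9.71, 9.63, 9.77, 9.66),
        "acc_y": (0.01, -0.4, 0.61, 0.08),
        "acc_z": (0.23, -1.44, 1.06, 0.36),
        "gyro_x": (0.0, 0.0, 0.0, 0.03),
        "gyro_y": (0.0, -0.06, 0.06, -0.03),
        "gyro_z": (0.0, -0.06, 0.06, 0.0),
        "roll": (13.0, -56.4, 154.9, 25.11),
        "pitch": (-81.2, -85.8, -79.1, -80.14),
        "yaw": (17.2, -122.85, 62.7, -23.05),
    },
    "eoL": {
        "acc_x": (9.69, 9.62, 9.74, 9.66),
        "acc_y": (0.47, -1.18, 1.07, -0.52),
        "acc_z": (0.04, -1.25, 1.02, 0.4),
        "gyro_x": (0.0, 0.0, 0.0, 0.0),
        "gyro_y": (0.0, -0.12, 0.12, 0.0),
        "gyro_z": (0.0, 0.0, 0.0, 0.0),
        "roll": (25.3, -128.4, 49.4, -35.51),
        "pitch": (-80.8, -82.8, -80.0, -80.26),
        "yaw": (-43.5, -109.5, 89.9, -1.9),
    },
    "ecR": {
        "acc_x": (9.65, 9.55, 9.76, 9.65),
        "acc_y": (-0.02, -0.42, 0.38, -0.08),
        "acc_z": (0.32, -1.13, 1.41, 0.33),
        "gyro_x": (-0.06, -0.06, 0.06, 0.0),
        "gyro_y": (0.0, -0.06, 0.12, 0.0),
        "gyro_z": (0.0, -0.12, 0.0, 0.0),
        "roll": (-1.8, -82.9, 80.2, -18.77),
        "pitch": (-79.6, -83.3, -77.1, -80.5),
        "yaw": (-57.5, -114.8, 34.05, -47.83),
    },
    "ecL": {
        "acc_x": (9.69, 9.55, 9.71, 9.68),
        "acc_y": (-0.03, -1.41, 0.35, -0.64),
        "acc_z": (-1.12, -1.88, -0.06, 0.02),
        "gyro_x": (0.0, -0.12, 0.06, -0.05),
        "gyro_y": (0.06, 0.0, 0.18, 0.03),
        "gyro_z": (0.0, -0.06, 0.06, 0.0),
        "roll": (-74.5, -140.2, 152.5, -33.63),
        "pitch": (-79.6, -81.3, -75.7, -80.4),
        "yaw": (15.5, -70.7, 54.4, 3.48),
    },
}

#: IQR -> SD conversion for a normal distribution.
_IQR_TO_SD = 1.349
#: Spread floor (native channel units) so that channels whose reference
#: quartiles sit at the sensor resolution remain non-degenerate.
DEFAULT_SPREAD_FLOOR = 0.03

DEFAULT_N_ADDICTED = 19
DEFAULT_N_NON_ADDICTED = 28


# ---------------------------------------------------------------------------
# Parameter sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SwayGeneratorParams:
    """Controls one condition x group CoP generator.

    hurst sets the temporal persistence (FD = 2 - hurst for the raw path);
    target_path_ml/ap are the desired expected per-axis path lengths in mm
    (None -> looked up in DEFAULT_PATH_TARGETS); subject_sigma is the SD of
    the log-normal between-subject factor applied to both targets by
    gen_cohort; smoothing_cutoff is the low-pass corner in Hz.
    """

    fs: float = DEFAULT_FS
    duration: float = DEFAULT_DURATION
    hurst: float = 0.7
    target_path_ml: float | None = None
    target_path_ap: float | None = None
    smoothing_cutoff: float = 10.0
    subject_sigma: float = 0.25
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.hurst < 1:
            raise ParameterError(f"hurst must lie in (0, 1), got {self.hurst}")
        for name in ("target_path_ml", "target_path_ap"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ParameterError(f"{name} must be > 0, got {v}")
        n = self.fs * self.duration
        if abs(n - round(n)) > 1e-9 or n < 2:
            raise ParameterError("fs * duration must be an integer sample count >= 2")
        if not 0 < self.smoothing_cutoff < self.fs / 2:
            raise ParameterError("smoothing_cutoff must lie in (0, fs/2)")
        if self.subject_sigma < 0:
            raise ParameterError("subject_sigma must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    def targets_for(self, group: str, condition: str) -> tuple[float, float]:
        defaults = DEFAULT_PATH_TARGETS[condition][group]
        ml = self.target_path_ml if self.target_path_ml is not None else defaults[0]
        ap = self.target_path_ap if self.target_path_ap is not None else defaults[1]
        return ml, ap


@dataclass(frozen=True)
class IMUGeneratorParams:
    """Per-channel baselines/spreads and additive offsets for the dependent group.

    spread drives both the between-subject scatter of the channel level and
    (scaled by within_frac) the within-trial noise, so zero spread yields an
    exactly constant channel at its baseline.
    """

    baselines: dict[str, float] = field(default_factory=dict)
    spreads: dict[str, float] = field(default_factory=dict)
    addicted_offsets: dict[str, float] = field(default_factory=dict)
    within_frac: float = 0.5
    fs: float = DEFAULT_FS
    duration: float = DEFAULT_DURATION
    seed: int | None = None

    def __post_init__(self) -> None:
        for name, v in self.spreads.items():
            if v < 0:
                raise ParameterError(f"spread for {name} must be >= 0, got {v}")
        if self.within_frac < 0:
            raise ParameterError("within_frac must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    @classmethod
    def from_reference_cohort(
        cls, condition: str, *, spread_floor: float = DEFAULT_SPREAD_FLOOR, **kwargs
    ) -> "IMUGeneratorParams":
        """Defaults for one condition from the reference IMU median grid."""
        ref = DEFAULT_IMU_REFERENCE[condition]
        baselines = {c: ref[c][0] for c in IMU_CHANNELS}
        spreads = {
            c: max((ref[c][2] - ref[c][1]) / _IQR_TO_SD, spread_floor)
            for c in IMU_CHANNELS
        }
        offsets = {c: ref[c][3] - ref[c][0] for c in IMU_CHANNELS}
        return cls(baselines=baselines, spreads=spreads, addicted_offsets=offsets, **kwargs)


@dataclass
class Subject:
    subject_id: str
    group: str
    cop: dict[str, CoPTrial] = field(default_factory=dict)
    imu: dict[str, IMUTrial] = field(default_factory=dict)


@dataclass
class Cohort:
    subjects: list[Subject]
    master_seed: int

    def __post_init__(self) -> None:
        for s in self.subjects:
            if s.group not in GROUPS:
                raise ValidationError(f"unknown group {s.group!r}")

    @property
    def n_addicted(self) -> int:
        return sum(1 for s in self.subjects if s.group == "addicted")

    @property
    def n_non_addicted(self) -> int:
        return sum(1 for s in self.subjects if s.group == "non_addicted")


# ---------------------------------------------------------------------------
# Fractional Brownian motion (Davies-Harte circulant embedding)
# ---------------------------------------------------------------------------

def gen_fbm(n: int, hurst: float, seed: int) -> np.ndarray:
    """Zero-mean fBm path of length n with Hurst exponent H.

    Exact synthesis: fractional Gaussian noise from circulant embedding of
    its autocovariance, then a cumulative sum. FD of the path is 2 - H.
    """
    if not 0 < hurst < 1:
        raise ParameterError(f"hurst must lie in (0, 1), got {hurst}")
    if n < 2:
        raise ParameterError(f"n must be >= 2, got {n}")
    rng = np.random.default_rng(seed)
    h2 = 2.0 * hurst
    k = np.arange(n, dtype=float)
    gamma = 0.5 * (np.abs(k + 1) ** h2 - 2.0 * np.abs(k) ** h2 + np.abs(k - 1) ** h2)
    row = np.concatenate([gamma, [0.0], gamma[-1:0:-1]])  # circulant first row, len 2n
    eigs = np.fft.fft(row).real
    eigs = np.clip(eigs, 0.0, None)  # guard tiny negative rounding errors
    m = 2 * n
    w = np.zeros(m, dtype=complex)
    w[0] = np.sqrt(eigs[0] / m) * rng.standard_normal()
    w[n] = np.sqrt(eigs[n] / m) * rng.standard_normal()
    u = rng.standard_normal(n - 1)
    v = rng.standard_normal(n - 1)
    w[1:n] = np.sqrt(eigs[1:n] / (2 * m)) * (u + 1j * v)
    w[n + 1:] = np.conj(w[1:n][::-1])
    fgn = np.fft.fft(w)[:n].real
    path = np.cumsum(fgn)
    return path - path.mean()


# ---------------------------------------------------------------------------
# Trial generators
# ---------------------------------------------------------------------------

def _lowpass(x: np.ndarray, cutoff: float, fs: float) -> np.ndarray:
    b, a = sp_signal.butter(4, cutoff, btype="low", fs=fs)
    return sp_signal.filtfilt(b, a, x)


def _scaled_axis(
    n: int, hurst: float, cutoff: float, fs: float, target_path: float, seed: int
) -> np.ndarray:
    raw = gen_fbm(n, hurst, seed)
    smooth = _lowpass(raw, cutoff, fs)
    # Expected path length of a series with iid-Gaussian-like increments:
    # E[sum |dx|] = (n-1) * sd(dx) * sqrt(2/pi); rescale analytically.
    sd_inc = float(np.std(np.diff(smooth)))
    if sd_inc == 0.0:
        raise ParameterError("degenerate smoothed path (zero increment SD)")
    expected = (n - 1) * sd_inc * np.sqrt(2.0 / np.pi)
    return smooth * (target_path / expected)


def gen_cop_trial(
    group: str,
    condition: str,
    params: SwayGeneratorParams = SwayGeneratorParams(),
    seed: int | None = None,
    *,
    subject_id: str = "synthetic",
) -> CoPTrial:
    """One synthetic CoP trial whose expected axis path lengths hit the
    condition x group targets."""
    if seed is None:
        seed = params.seed if params.seed is not None else 0
    target_ml, target_ap = params.targets_for(group, condition)
    n = params.n_samples
    ml = _scaled_axis(n, params.hurst, params.smoothing_cutoff, params.fs, target_ml, seed)
    ap = _scaled_axis(
        n, params.hurst, params.smoothing_cutoff, params.fs, target_ap, seed + 1_000_003
    )
    return CoPTrial(
        subject_id=subject_id, group=group, condition=condition, ml=ml, ap=ap, fs=params.fs
    )


def _ar1_noise(rng: np.random.Generator, n: int, phi: float = 0.95) -> np.ndarray:
    """Unit-SD smooth noise: stationary AR(1) with coefficient phi."""
    eps = rng.standard_normal(n)
    x0 = eps[0]  # stationary start
    innov = eps[1:] * np.sqrt(1.0 - phi * phi)
    rest, _ = sp_signal.lfilter([1.0], [1.0, -phi], innov, zi=np.array([phi * x0]))
    return np.concatenate([[x0], rest])


def gen_imu_trial(
    group: str,
    condition: str,
    params: IMUGeneratorParams | None = None,
    seed: int | None = None,
    *,
    subject_id: str = "synthetic",
) -> IMUTrial:
    """One synthetic IMU trial: per-channel level (baseline + group offset +
    between-subject scatter) plus smooth within-trial noise."""
    if params is None:
        params = IMUGeneratorParams.from_reference_cohort(condition)
    if seed is None:
        seed = params.seed if params.seed is not None else 0
    rng = np.random.default_rng(seed)
    n = params.n_samples
    channels: dict[str, np.ndarray] = {}
    for name in IMU_CHANNELS:
        baseline = params.baselines.get(name, 0.0)
        spread = params.spreads.get(name, 0.0)
        offset = params.addicted_offsets.get(name, 0.0) if group == "addicted" else 0.0
        level = baseline + offset + spread * rng.standard_normal()
        if spread == 0.0:
            channels[name] = np.full(n, baseline + offset)
        else:
            channels[name] = level + params.within_frac * spread * _ar1_noise(rng, n)
    return IMUTrial(
        subject_id=subject_id, group=group, condition=condition, channels=channels, fs=params.fs
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def child_seed(master_seed: int, *key: int) -> int:
    """Stable per-trial seed: SeedSequence over (master_seed, *key), < 2^31."""
    ss = np.random.SeedSequence([int(master_seed), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % (2**31))


def gen_cohort(
    n_addicted: int = DEFAULT_N_ADDICTED,
    n_non_addicted: int = DEFAULT_N_NON_ADDICTED,
    sway: SwayGeneratorParams = SwayGeneratorParams(),
    imu: dict[str, IMUGeneratorParams] | None = None,
    master_seed: int = 0,
    conditions: tuple[str, ...] = CONDITIONS,
    with_imu: bool = True,
) -> Cohort:
    """Full two-group cohort: one CoP (and optionally IMU) trial per subject
    per condition, reproducibly seeded from master_seed."""
    if n_addicted < 2 or n_non_addicted < 2:
        raise ParameterError("each group needs at least 2 subjects")
    for c in conditions:
        if c not in CONDITIONS:
            raise ParameterError(f"unknown condition {c!r}")
    if imu is None and with_imu:
        imu = {c: IMUGeneratorParams.from_reference_cohort(c) for c in conditions}
    labels = [("addicted", i, f"A{i + 1:02d}") for i in range(n_addicted)]
    labels += [("non_addicted", i, f"N{i + 1:02d}") for i in range(n_non_addicted)]
    subjects: list[Subject] = []
    for subj_idx, (group, _, sid) in enumerate(labels):
        subj = Subject(subject_id=sid, group=group)
        for cond_idx, cond in enumerate(conditions):
            factor_rng = np.random.default_rng(child_seed(master_seed, subj_idx, cond_idx, 2))
            factor = float(np.exp(sway.subject_sigma * factor_rng.standard_normal()))
            base_ml, base_ap = sway.targets_for(group, cond)
            subj_params = dataclasses.replace(
                sway, target_path_ml=base_ml * factor, target_path_ap=base_ap * factor
            )
            subj.cop[cond] = gen_cop_trial(
                group, cond, subj_params,
                seed=child_seed(master_seed, subj_idx, cond_idx, 0),
                subject_id=sid,
            )
            if with_imu:
                subj.imu[cond] = gen_imu_trial(
                    group, cond, imu[cond],
                    seed=child_seed(master_seed, subj_idx, cond_idx, 1),
                    subject_id=sid,
                )
        subjects.append(subj)
    return Cohort(subjects=subjects, master_seed=master_seed)


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write the CSV layout (one CoP + one IMU file per subject x condition)
    plus a manifest.json describing the cohort."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for subj in cohort.subjects:
        for cond, trial in subj.cop.items():
            path = outdir / f"{subj.subject_id}_{cond}_cop.csv"
            write_cop_csv(trial, path)
            entry = {"subject": subj.subject_id, "group": subj.group, "condition": cond,
                     "cop": path.name}
            if cond in subj.imu:
                ipath = outdir / f"{subj.subject_id}_{cond}_imu.csv"
                write_imu_csv(subj.imu[cond], ipath)
                entry["imu"] = ipath.name
            entries.append(entry)
    manifest = {
        "master_seed": cohort.master_seed,
        "n_addicted": cohort.n_addicted,
        "n_non_addicted": cohort.n_non_addicted,
        "trials": entries,
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir


def load_cohort(indir: str | Path) -> Cohort:
    """Read a cohort directory written by :func:`write_cohort`."""
    indir = Path(indir)
    manifest_path = indir / "manifest.json"
    if not manifest_path.exists():
        raise ValidationError(f"{indir}: manifest.json not found")
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = json.load(fh)
    subjects: dict[str, Subject] = {}
    for entry in manifest["trials"]:
        sid, group, cond = entry["subject"], entry["group"], entry["condition"]
        cop_path = indir / entry["cop"]
        if not cop_path.exists():
            raise ValidationError(f"missing trial file for subject {sid!r}: {cop_path.name}")
        subj = subjects.setdefault(sid, Subject(subject_id=sid, group=group))
        subj.cop[cond] = read_cop_csv(cop_path)
        if "imu" in entry:
            imu_path = indir / entry["imu"]
            if not imu_path.exists():
                raise ValidationError(
                    f"missing trial file for subject {sid!r}: {imu_path.name}"
                )
            subj.imu[cond] = read_imu_csv(imu_path)
    return Cohort(subjects=list(subjects.values()), master_seed=int(manifest["master_seed"]))
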