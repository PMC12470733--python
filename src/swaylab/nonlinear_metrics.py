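"""Nonlinear sway estimators: sample entropy, Higuchi fractal dimension,
and the Wolf largest Lyapunov exponent.

All three operate on a single-axis CoP displacement series and are
deterministic given the input and their parameters.

Conventions
-----------
* SampEn uses the Chebyshev (max-norm) template distance, excludes
  self-matches, and counts matching template pairs among the N-m templates
  that all admit an (m+1)-length extension; tolerance r = r_frac * SD of the
  series, so the estimate is invariant under affine rescaling of the signal.
* Higuchi curve lengths follow the exact normalization
  L(m,k) = [sum |x_{m+ik} - x_{m+(i-1)k}|] * (N-1) / (int((N-m)/k) * k^2),
  averaged over m = 1..k; FD is the unweighted least-squares slope of
  ln L(k) against ln(1/k) over k = 1..k_max.
* The Wolf exponent delay-embeds the series, tracks the separation between
  a reference trajectory and its nearest admissible neighbor (outside a
  Theiler window), accumulates ln(d_after/d_before) over fixed evolution
  intervals, and replaces the neighbor (preferring one that preserves the
  orientation of the separation vector) whenever the separation exceeds a
  fraction of the data range. The result is the mean log-divergence per
  evolved sample (natural log), so its absolute scale depends on the
  embedding parameters; those are echoed into pipeline metadata.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .io_model import (
    CoPTrial,
    DegenerateInputError,
    EstimationError,
    ParameterError,
    ValidationError,
)


@dataclass(frozen=True)
class SampEnParams:
    """Template length m and tolerance fraction r (of the signal SD)."""

    m: int = 2
    r_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ParameterError(f"m must be >= 1, got {self.m}")
        if not self.r_frac > 0:
            raise ParameterError(f"r_frac must be > 0, got {self.r_frac}")


@dataclass(frozen=True)
class HiguchiParams:
    k_max: int = 100

    def __post_init__(self) -> None:
        if self.k_max < 2:
            raise ParameterError(f"k_max must be >= 2, got {self.k_max}")

    def validate_for_length(self, n: int) -> None:
        if not self.k_max < n / 2:
            raise ParameterError(f"k_max={self.k_max} must be < N/2 = {n / 2}")


@dataclass(frozen=True)
class WolfParams:
    """Phase-space reconstruction and divergence-tracking knobs.

    delay is in samples (10 samples = 0.1 s at 100 Hz); theiler defaults to
    delay * embed_dim; max_sep_frac is the replacement trigger as a fraction
    of the scalar data range; min_sep is a noise floor on admissible
    neighbor distances.
    """

    embed_dim: int = 5
    delay: int = 10
    evolve_steps: int = 3
    min_sep: float = 0.0
    max_sep_frac: float = 0.1
    theiler: int | None = None

    def __post_init__(self) -> None:
        if self.embed_dim < 2:
            raise ParameterError(f"embed_dim must be >= 2, got {self.embed_dim}")
        if self.delay < 1:
            raise ParameterError(f"delay must be >= 1, got {self.delay}")
        if self.evolve_steps < 1:
            raise ParameterError(f"evolve_steps must be >= 1, got {self.evolve_steps}")
        if self.min_sep < 0:
            raise ParameterError("min_sep must be >= 0")
        if not 0 < self.max_sep_frac <= 1:
            raise ParameterError("max_sep_frac must be in (0, 1]")

    @property
    def theiler_window(self) -> int:
        return self.delay * self.embed_dim if self.theiler is None else self.theiler


# ---------------------------------------------------------------------------
# Sample entropy
# ---------------------------------------------------------------------------

@njit(cache=False)
def _sampen_pair_counts(x: np.ndarray, m: int, r: float):  # pragma: no cover - jitted
    n = x.shape[0]
    nt = n - m  # templates that admit an (m+1)-extension
    b = 0  # m-length matches
    a = 0  # (m+1)-length matches
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            match = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    match = False
                    break
            if match:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b


def sample_entropy(series, params: SampEnParams = SampEnParams()) -> float:
    """SampEn(m, r) = -ln(B^{m+1}(r) / B^m(r)) with r = r_frac * SD.

    Returns +inf if no (m+1)-length template pair matches (perfectly
    unpredictable at tolerance r); raises on a constant series.
    """
    x = np.ascontiguousarray(series, dtype=float)
    if x.ndim != 1 or len(x) < params.m + 2:
        raise ValidationError(f"series must be 1-D with length >= m+2 = {params.m + 2}")
    sd = float(np.std(x))
    if sd == 0.0:
        raise DegenerateInputError("constant series: SampEn tolerance r = 0")
    r = params.r_frac * sd
    a, b = _sampen_pair_counts(x, params.m, r)
    if b == 0 or a == 0:
        return math.inf
    return float(-math.log(a / b))


# ---------------------------------------------------------------------------
# Higuchi fractal dimension
# ---------------------------------------------------------------------------

def higuchi_curve_length(series, k: int) -> float:
    """Average normalized curve length L(k) over the k sub-series offsets."""
    x = np.asarray(series, dtype=float)
    n = len(x)
    if not 1 <= k <= n - 1:
        raise ParameterError(f"k={k} outside [1, N-1] for N={n}")
    lengths = []
    excluded = 0
    for m in range(1, k + 1):
        nseg = (n - m) // k
        if nseg == 0:
            excluded += 1
            continue
        sub = x[m - 1:: k]
        total = float(np.sum(np.abs(np.diff(sub[: nseg + 1]))))
        lengths.append(total * (n - 1) / (nseg * k * k))
    if not lengths:
        raise ParameterError(f"k={k} leaves no valid sub-series for N={n}")
    if excluded:
        warnings.warn(
            f"higuchi_curve_length: {excluded} of {k} offsets excluded at k={k}",
            stacklevel=2,
        )
    return float(np.mean(lengths))


def higuchi_fd(series, params: HiguchiParams = HiguchiParams()) -> float:
    """Fractal dimension as the slope of ln L(k) vs ln(1/k), k = 1..k_max.

    1 for a smooth line, 2 for uncorrelated noise, 2 - H for fractional
    Brownian motion with Hurst exponent H. Values outside [1, 2] are
    possible on short or pathological inputs and are flagged downstream.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    params.validate_for_length(n)
    if np.ptp(x) == 0.0:
        raise DegenerateInputError("constant series has no curve-length scaling")
    ks = np.arange(1, params.k_max + 1)
    lk = np.array([higuchi_curve_length(x, int(k)) for k in ks])
    if np.any(lk <= 0):
        raise DegenerateInputError("non-positive curve length; series too regular")
    slope, _ = np.polyfit(np.log(1.0 / ks), np.log(lk), 1)
    return float(slope)


# ---------------------------------------------------------------------------
# Wolf largest Lyapunov exponent
# ---------------------------------------------------------------------------

@njit(cache=False)
def _dist(emb: np.ndarray, i: int, j: int) -> float:  # pragma: no cover - jitted
    s = 0.0
    for k in range(emb.shape[1]):
        d = emb[i, k] - emb[j, k]
        s += d * d
    return math.sqrt(s)


@njit(cache=False)
def _find_nearest(emb, i, theiler, min_sep, exclude, cmax):  # pragma: no cover - jitted
    """Nearest admissible neighbor among indices [0, cmax) — the bound keeps
    only points that can still be evolved forward."""
    best = -1
    best_d = 1e300
    for c in range(cmax):
        if abs(c - i) <= theiler or c == exclude:
            continue
        d = _dist(emb, i, c)
        if d > min_sep and d < best_d:
            best_d = d
            best = c
    return best


@njit(cache=False)
def _find_replacement(emb, i, j, theiler, min_sep, max_sep, cmax):  # pragma: no cover
    """Closest admissible point to emb[i] that best preserves the orientation
    of the current separation vector emb[j] - emb[i]; falls back to the
    plain nearest neighbor when nothing lies within max_sep."""
    dim = emb.shape[1]
    ref_norm = _dist(emb, i, j)
    best = -1
    best_cos = -2.0
    best_d = 1e300
    for c in range(cmax):
        if abs(c - i) <= theiler or c == j:
            continue
        d = _dist(emb, i, c)
        if d <= min_sep or d > max_sep:
            continue
        dot = 0.0
        for k in range(dim):
            dot += (emb[c, k] - emb[i, k]) * (emb[j, k] - emb[i, k])
        cosang = dot / (d * ref_norm) if ref_norm > 0 and d > 0 else -2.0
        if cosang > best_cos or (cosang == best_cos and d < best_d):
            best_cos = cosang
            best_d = d
            best = c
    if best < 0:
        best = _find_nearest(emb, i, theiler, min_sep, j, cmax)
    return best


@njit(cache=False)
def _wolf_track(emb, evolve, theiler, min_sep, max_sep):  # pragma: no cover
    npts = emb.shape[0]
    cmax = npts - evolve  # only neighbors that can still be evolved
    total_log = 0.0
    total_steps = 0
    i = 0
    j = _find_nearest(emb, i, theiler, min_sep, -1, cmax)
    if j < 0:
        return 0.0, 0
    while i + evolve < npts:
        d0 = _dist(emb, i, j)
        if d0 <= min_sep or d0 == 0.0:
            j = _find_nearest(emb, i, theiler, min_sep, j, cmax)
            if j < 0:
                break
            continue
        d1 = _dist(emb, i + evolve, j + evolve)
        if d1 > 0.0:
            total_log += math.log(d1 / d0)
            total_steps += evolve
        i += evolve
        j += evolve
        if i + evolve >= npts:
            break
        if d1 > max_sep or j + evolve >= npts:
            jn = _find_replacement(emb, i, j, theiler, min_sep, max_sep, cmax)
            if jn < 0:
                break
            j = jn
    return total_log, total_steps


def _delay_embed(x: np.ndarray, dim: int, delay: int) -> np.ndarray:
    npts = len(x) - (dim - 1) * delay
    emb = np.empty((npts, dim), dtype=float)
    for k in range(dim):
        emb[:, k] = x[k * delay: k * delay + npts]
    return emb


def wolf_lyapunov(series, params: WolfParams = WolfParams()) -> float:
    """Dominant Lyapunov exponent (natural log per evolved sample).

    Positive values indicate exponential divergence of nearby reconstructed
    trajectories (local instability of sway); values near zero indicate
    neutral, e.g. periodic, dynamics.
    """
    x = np.ascontiguousarray(series, dtype=float)
    min_len = (params.embed_dim - 1) * params.delay + 10 * params.evolve_steps
    if x.ndim != 1 or len(x) < min_len:
        raise ValidationError(f"series too short: need >= {min_len} samples")
    data_range = float(np.ptp(x))
    if data_range == 0.0:
        raise DegenerateInputError("constant series has no phase-space structure")
    emb = _delay_embed(x, params.embed_dim, params.delay)
    max_sep = params.max_sep_frac * data_range
    total_log, total_steps = _wolf_track(
        emb, params.evolve_steps, params.theiler_window, params.min_sep, max_sep
    )
    if total_steps == 0:
        raise EstimationError("no admissible neighbor found; cannot track divergence")
    return float(total_log / total_steps)


# ---------------------------------------------------------------------------
# Per-trial driver
# ---------------------------------------------------------------------------

# Estimator errors are re-raised tagged with the failing axis, without
# masking the original error class.
def _tagged(trial_axis: str, exc: Exception) -> Exception:
    exc.args = (f"[axis={trial_axis}] " + (exc.args[0] if exc.args else ""),) + exc.args[1:]
    return exc


def sway_nonlinear_metrics(
    trial: CoPTrial,
    sampen: SampEnParams = SampEnParams(),
    higuchi: HiguchiParams = HiguchiParams(),
    wolf: WolfParams = WolfParams(),
) -> dict[str, float]:
    """The six nonlinear outcomes of one trial: SampEn/FD/LyE on ML and AP."""
    out: dict[str, float] = {}
    for axis, x in (("ml", trial.ml), ("ap", trial.ap)):
        try:
            out[f"sampen_{axis}"] = sample_entropy(x, sampen)
            out[f"fd_{axis}"] = higuchi_fd(x, higuchi)
            out[f"lye_{axis}"] = wolf_lyapunov(x, wolf)
        except Exception as exc:
            raise _tagged(axis, exc) from None
    return out
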