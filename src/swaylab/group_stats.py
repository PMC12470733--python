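"""Two-group nonparametric comparison stage.

Each outcome variable is compared between groups, per stance condition, with
the Mann-Whitney U test; the Z score comes from the tie-corrected normal
approximation (continuity-corrected by default) and yields the effect size
r = Z / sqrt(N), classified as small (|r| < 0.3), medium (0.3 <= |r| <= 0.5)
or large (|r| > 0.5). A Shapiro-Wilk normality check is reported per
variable but is advisory only: the comparison is always rank-based, so one
uniform test applies whether or not a variable happens to look normal.

Sign convention: Z (and hence r) is positive when the first group tends to
larger values. The pipeline passes the non-dependent group first, so a
larger median in the dependence-history group produces negative Z and r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import (
    DegenerateInputError,
    GroupComparison,
    ParameterError,
    ValidationError,
)


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    use_continuity: bool = True
    tie_correction: bool = True
    #: optional Holm step-down correction across a table (off: mirrors the
    #: uncorrected per-test screen convention)
    holm: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ParameterError(f"alpha must lie in (0, 1), got {self.alpha}")


def shapiro_normality(values, alpha: float = 0.05) -> bool:
    """True iff the Shapiro-Wilk test does not reject normality at alpha."""
    x = np.asarray(values, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValidationError(f"Shapiro-Wilk needs 3 <= n <= 5000, got n={len(x)}")
    if np.ptp(x) == 0.0:
        raise DegenerateInputError("constant sample: normality test undefined")
    return bool(stats.shapiro(x).pvalue >= alpha)


def _z_from_u(u: float, n1: int, n2: int, pooled: np.ndarray, config: StatsConfig) -> float:
    """Tie- and continuity-corrected normal approximation Z for U (group-1 wins)."""
    n = n1 + n2
    mu = n1 * n2 / 2.0
    var = n1 * n2 * (n + 1) / 12.0
    if config.tie_correction:
        _, counts = np.unique(pooled, return_counts=True)
        ties = counts[counts > 1]
        if ties.size:
            var -= n1 * n2 * np.sum(ties**3 - ties) / (12.0 * n * (n - 1))
    if var <= 0:
        return 0.0
    diff = u - mu
    if config.use_continuity and diff != 0.0:
        diff -= 0.5 * math.copysign(1.0, diff)
    return float(diff / math.sqrt(var))


def mann_whitney(a, b, config: StatsConfig = StatsConfig()) -> tuple[float, float, float]:
    """(U, Z, p) for two independent samples.

    U is the statistic of sample ``a`` (count of (a, b) pairs with a > b,
    ties counted half); Z > 0 when ``a`` tends larger. p is two-sided, via
    exact enumeration for small untied samples and the normal approximation
    otherwise (scipy's automatic policy).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValidationError("both groups must be non-empty")
    if len(a) + len(b) < 3:
        raise ValidationError("need at least 3 observations in total")
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="auto", use_continuity=config.use_continuity
    )
    z = _z_from_u(float(res.statistic), len(a), len(b), np.concatenate([a, b]), config)
    return float(res.statistic), z, float(res.pvalue)


def effect_size_r(Z: float, N: int) -> float:
    """r = Z / sqrt(N); reported rounded only at the output layer."""
    if N <= 0:
        raise ValidationError(f"N must be >= 1, got {N}")
    return float(Z / math.sqrt(N))


def classify_effect(r: float) -> str:
    """small / medium / large by |r| with the 0.3 and 0.5 cutpoints
    (both boundaries belong to 'medium')."""
    if not math.isfinite(r):
        raise ValidationError(f"r must be finite, got {r}")
    a = abs(r)
    if a < 0.3:
        return "small"
    if a <= 0.5:
        return "medium"
    return "large"


def _median_quartiles(x: np.ndarray) -> tuple[float, float, float]:
    # linear interpolation between order statistics (numpy default)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return float(med), float(q1), float(q3)


def compare_groups(
    table: pd.DataFrame,
    variable: str,
    condition: str,
    config: StatsConfig = StatsConfig(),
    *,
    group_a: str = "non_addicted",
    group_b: str = "addicted",
) -> GroupComparison:
    """One comparison row for a variable x condition stratum of a tidy
    metrics table (columns: subject_id, group, condition, <variables...>)."""
    stratum = table[table["condition"] == condition]
    a = stratum.loc[stratum["group"] == group_a, variable].to_numpy(float)
    b = stratum.loc[stratum["group"] == group_b, variable].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError(
            f"{variable} x {condition}: each group needs n >= 2 (got {len(a)}, {len(b)})"
        )
    u, z, p = mann_whitney(a, b, config)
    r = effect_size_r(z, len(a) + len(b))
    return GroupComparison(
        variable=variable,
        condition=condition,
        median_q1_q3_a=_median_quartiles(a),
        median_q1_q3_b=_median_quartiles(b),
        U=u,
        Z=z,
        p=p,
        r=r,
        effect_class=classify_effect(r),
        significant=bool(p < config.alpha),
    )


def compare_table(
    table: pd.DataFrame,
    variables: list[str],
    config: StatsConfig = StatsConfig(),
    *,
    conditions: list[str] | None = None,
    group_a: str = "non_addicted",
    group_b: str = "addicted",
) -> list[GroupComparison]:
    """All variable x condition comparisons, in table order.

    With ``config.holm`` the significance flags (not p itself) are
    re-derived from the Holm step-down procedure over the whole table.
    """
    conds = conditions or list(dict.fromkeys(table["condition"]))
    rows = [
        compare_groups(table, v, c, config, group_a=group_a, group_b=group_b)
        for c in conds
        for v in variables
    ]
    if config.holm and rows:
        order = np.argsort([row.p for row in rows])
        m = len(rows)
        running_max = 0.0
        for rank, idx in enumerate(order):
            adj = min(1.0, (m - rank) * rows[idx].p)
            running_max = max(running_max, adj)
            rows[idx].significant = bool(running_max < config.alpha)
    return rows
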