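"""Metric vs IMU correlation screen, stratified by group and condition.

Within each stratum every sway metric (4 linear + 6 nonlinear) is
correlated against every IMU channel median; only pairs significant at
alpha are kept, labeled with a strength band on |rho|:

    weak < 0.30 <= moderate < 0.50 <= strong <= 0.70 < very_strong,
    with |rho| >= 0.95 labeled near_perfect.

Spearman rank correlation is the default estimator — consistent with the
rank-based comparison stage and insensitive to monotone transformations;
Pearson is available via ``method``. No multiplicity correction is applied
across the metric x channel grid: this is an exploratory screen and the
expected false-hit count is alpha x n_pairs under the null.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import CorrelationHit, DegenerateInputError, ValidationError


def correlate_pair(x, y, method: str = "spearman") -> tuple[float, float]:
    """Correlation coefficient in [-1, 1] and its two-sided p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError(f"length mismatch: {len(x)} != {len(y)}")
    if len(x) < 4:
        raise ValidationError(f"need n >= 4 pairs, got {len(x)}")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise DegenerateInputError("constant input: correlation undefined")
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
    elif method == "pearson":
        rho, p = stats.pearsonr(x, y)
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    return float(rho), float(p)


def classify_correlation(rho: float) -> str:
    a = abs(rho)
    if a > 1.0:
        raise ValidationError(f"|rho| must be <= 1, got {rho}")
    if a >= 0.95:
        return "near_perfect"
    if a > 0.7:
        return "very_strong"
    if a >= 0.5:
        return "strong"
    if a >= 0.3:
        return "moderate"
    return "weak"


def correlation_screen(
    metrics: pd.DataFrame,
    imu: pd.DataFrame,
    group: str,
    condition: str,
    alpha: float = 0.05,
    *,
    method: str = "spearman",
    metric_names: list[str] | None = None,
    channel_names: list[str] | None = None,
) -> list[CorrelationHit]:
    """All significant (metric, channel) pairs in one group x condition
    stratum, sorted by |rho| descending.

    ``metrics`` and ``imu`` are tidy per-subject tables (columns:
    subject_id, group, condition, <values...>) aligned on subject_id.
    Degenerate (constant) columns are skipped with a warning.
    """
    ms = metrics[(metrics["group"] == group) & (metrics["condition"] == condition)]
    im = imu[(imu["group"] == group) & (imu["condition"] == condition)]
    merged = ms.merge(im, on=["subject_id", "group", "condition"], suffixes=("", "_imu"))
    if len(merged) < 4:
        raise ValidationError(
            f"stratum {group} x {condition} too small: n={len(merged)} < 4"
        )
    id_cols = {"subject_id", "group", "condition"}
    mnames = metric_names or [c for c in ms.columns if c not in id_cols]
    cnames = channel_names or [c for c in im.columns if c not in id_cols]
    hits: list[CorrelationHit] = []
    for metric in mnames:
        for channel in cnames:
            try:
                rho, p = correlate_pair(merged[metric], merged[channel], method=method)
            except DegenerateInputError:
                warnings.warn(
                    f"skipping degenerate pair {metric} x {channel} in "
                    f"{group} x {condition}",
                    stacklevel=2,
                )
                continue
            if p < alpha:
                hits.append(
                    CorrelationHit(
                        group=group,
                        condition=condition,
                        metric_name=metric,
                        imu_channel=channel,
                        rho=rho,
                        p=p,
                        strength=classify_correlation(rho),
                    )
                )
    hits.sort(key=lambda h: abs(h.rho), reverse=True)
    return hits
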