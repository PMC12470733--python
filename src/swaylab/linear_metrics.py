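"""Linear stabilometric parameters of a CoP trial.

Four summary measures of sway magnitude: per-axis path lengths (CoP_ML,
CoP_AP), the total planar path length (CoP_total), and the area of the 95%
prediction ellipse fitted to the (ML, AP) point cloud via its sample
covariance. All are computed on the raw displacement series at the native
sampling rate — no detrending, filtering or resampling.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .io_model import CoPTrial, DegenerateInputError, SwayLabError, ValidationError

#: 0.95 quantile of the chi-square distribution with 2 degrees of freedom.
CHI2_95_2DF = float(stats.chi2.ppf(0.95, df=2))


def path_length_axis(series) -> float:
    """Total variation of a single-axis displacement series (mm).

    sum_i |x_{i+1} - x_i|.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValidationError("path_length_axis needs a 1-D series of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite sample in series")
    return float(np.sum(np.abs(np.diff(x))))


def path_length_total(ml, ap) -> float:
    """Planar CoP path length: sum_i sqrt(dml_i^2 + dap_i^2) (mm)."""
    ml = np.asarray(ml, dtype=float)
    ap = np.asarray(ap, dtype=float)
    if len(ml) != len(ap):
        raise ValidationError(f"axis length mismatch: {len(ml)} != {len(ap)}")
    if len(ml) < 2:
        raise ValidationError("path_length_total needs length >= 2")
    if not (np.all(np.isfinite(ml)) and np.all(np.isfinite(ap))):
        raise ValidationError("non-finite sample in series")
    return float(np.sum(np.hypot(np.diff(ml), np.diff(ap))))


def ellipse_area_95(ml, ap, *, return_flag: bool = False):
    """Area of the 95% prediction ellipse of the (ml, ap) scatter (mm^2).

    area = pi * chi2_{2,0.95} * sqrt(det(S)) where S is the 2x2 sample
    covariance of the two axes. A singular (collinear) point cloud yields
    area 0 with a degeneracy flag.
    """
    ml = np.asarray(ml, dtype=float)
    ap = np.asarray(ap, dtype=float)
    if len(ml) != len(ap):
        raise ValidationError(f"axis length mismatch: {len(ml)} != {len(ap)}")
    if len(ml) < 3:
        raise ValidationError("ellipse_area_95 needs at least 3 samples")
    cov = np.cov(np.vstack([ml, ap]))
    det = float(np.linalg.det(cov))
    degenerate = det <= 0.0 or not np.isfinite(det)
    area = 0.0 if degenerate else float(np.pi * CHI2_95_2DF * np.sqrt(det))
    if return_flag:
        return area, degenerate
    return area


def sway_linear_metrics(trial: CoPTrial) -> dict[str, float]:
    """The four linear parameters of one trial, keyed by output name."""
    cop_ml = path_length_axis(trial.ml)
    cop_ap = path_length_axis(trial.ap)
    cop_total = path_length_total(trial.ml, trial.ap)
    ellipse = ellipse_area_95(trial.ml, trial.ap)
    return {
        "cop_total": cop_total,
        "cop_ml": cop_ml,
        "cop_ap": cop_ap,
        "ellipse": ellipse,
    }
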