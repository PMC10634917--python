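"""Robust univariate statistics shared across the pipeline.

``rout_outliers`` adapts the ROUT procedure (robust fit followed by
false-discovery-rate outlier tests) to a univariate sample: the robust "fit"
is the median, the robust residual scale (RSDR) is the 68.27th percentile of
the absolute residuals with a small-sample correction, and candidate outliers
are tested from the most extreme value inward against an FDR threshold at rate
Q. Only calibration properties (specificity/sensitivity), not the proprietary
reference implementation, define correctness.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats

from .errors import ParameterError

__all__ = ["OutlierResult", "rout_outliers", "fit_gaussian_1d"]

#: at most this fraction of values may be flagged (ROUT convention)
MAX_OUTLIER_FRACTION = 0.3


@dataclasses.dataclass
class OutlierResult:
    mask: np.ndarray  # True where flagged as outlier
    robust_center: float
    rsdr: float
    Q: float


def rout_outliers(values, Q: float = 0.001, side: str = "both") -> OutlierResult:
    """Flag univariate outliers with a robust-fit + FDR procedure.

    ``side="high"`` tests only values above the robust center (used for the
    "high outliers" smoothing of enrichment curves); ``side="both"`` tests both
    tails. The flag set is monotone: if a value is flagged, any value farther
    from the center on the same side is flagged too.
    """
    if side not in ("both", "high"):
        raise ParameterError(f"side must be 'both' or 'high', got {side!r}")
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 3:
        warnings.warn("rout_outliers needs >= 3 values; returning no outliers")
        return OutlierResult(np.zeros(n, bool), float(np.median(v)) if n else np.nan, np.nan, Q)
    center = float(np.median(v))
    resid = v - center
    abs_resid = np.abs(resid)
    # RSDR: percentile matching one SD for a normal sample, small-sample corrected
    rsdr = float(np.percentile(abs_resid, 68.27)) * n / max(n - 1, 1)
    mask = np.zeros(n, bool)

    tested = resid > 0 if side == "high" else np.ones(n, bool)
    if rsdr == 0.0:
        # majority of values identical: any residual on the tested side is extreme
        mask[tested & (abs_resid > 0)] = True
        return OutlierResult(mask, center, rsdr, Q)

    t = abs_resid / rsdr
    df = n - 1
    if side == "high":
        p = np.where(resid > 0, stats.t.sf(t, df), 1.0)
    else:
        p = 2.0 * stats.t.sf(t, df)
    order = np.argsort(p, kind="stable")
    order = order[tested[order]]
    k_max = int(np.floor(MAX_OUTLIER_FRACTION * n))
    n_flag = 0
    for rank, idx in enumerate(order[:k_max], start=1):
        if p[idx] <= Q * rank / n:
            n_flag = rank
    mask[order[:n_flag]] = True
    return OutlierResult(mask, center, rsdr, Q)


def fit_gaussian_1d(values) -> tuple[float, float]:
    """Maximum-likelihood normal fit: (sample mean, sample SD)."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ParameterError("fit_gaussian_1d needs >= 3 values")
    mu = float(v.mean())
    sd = float(v.std())
    if sd == 0.0:
        raise ParameterError("zero variance: degenerate gaussian fit")
    return mu, sd
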