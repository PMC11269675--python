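"""Adaptive-capacity composite and AHP weight analysis.

The composite scales each of the 15 socioeconomic/biophysical indicators to
[0, 1] with winsorised 5th/95th-percentile thresholds,

    AC_i = clamp((X − Q5) / (Q95 − Q5), 0, 1),

inverts indicators whose larger raw values mean *less* capacity, averages
them (equal weights by default) and min-max rescales the result across
regions. Expert pairwise-comparison matrices can replace the equal weights
through the analytic hierarchy process: weights are the normalised
principal eigenvector, gated by Saaty's consistency ratio CR < 0.10.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import DEFAULT_DIRECTIONS, INDICATOR_COLUMNS, INDICATOR_DIMENSIONS

__all__ = [
    "percentile_scale",
    "aggregate_capacity",
    "capacity_scores",
    "ahp_weights",
    "check_consistency",
    "weight_concordance",
    "SAATY_RI",
]

# Saaty random-consistency index, n = 1..15
SAATY_RI = (0.0, 0.0, 0.58, 0.90, 1.12, 1.24, 1.32, 1.41, 1.45, 1.49,
            1.51, 1.54, 1.56, 1.57, 1.59)


def percentile_scale(column, direction: str = "higher_is_better") -> np.ndarray:
    """Winsorised percentile scaling of one indicator column to [0, 1].

    Values at the 5th percentile map to 0, at the 95th to 1; values
    outside are clamped so outliers cannot dominate the composite.
    ``lower_is_better`` columns are inverted after scaling. Percentiles use
    linear interpolation between order statistics. A degenerate column
    (Q5 == Q95) maps to all zeros.
    """
    x = np.asarray(column, dtype=float)
    if x.size == 0 or np.all(np.isnan(x)):
        raise ValueError("indicator column is empty or all-missing")
    if direction not in ("higher_is_better", "lower_is_better"):
        raise ValueError(f"unknown direction {direction!r}")
    q5, q95 = np.percentile(x[~np.isnan(x)], [5.0, 95.0])
    if q95 == q5:
        return np.zeros_like(x)
    scaled = np.clip((x - q5) / (q95 - q5), 0.0, 1.0)
    return 1.0 - scaled if direction == "lower_is_better" else scaled


def aggregate_capacity(scaled: pd.DataFrame, weights=None,
                       normalize: bool = True) -> pd.DataFrame:
    """Weighted mean of scaled indicators, optionally min-max rescaled.

    ``scaled`` holds region_id plus the per-indicator [0, 1] scores.
    Equal weights are the default; a weight vector (matching the indicator
    columns in order) switches to AHP or custom weighting. Dimension means
    (social, physical, natural, human, financial) are attached for
    reporting.
    """
    cols = [c for c in scaled.columns if c != "region_id"]
    w = (np.full(len(cols), 1.0 / len(cols)) if weights is None
         else np.asarray(weights, dtype=float))
    if len(w) != len(cols):
        raise ValueError(f"{len(w)} weights for {len(cols)} indicator columns")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative and not all zero")
    w = w / w.sum()
    mat = scaled[cols].to_numpy(dtype=float)
    out = pd.DataFrame({"region_id": scaled["region_id"]})
    raw = mat @ w
    out["ac_raw"] = raw
    if normalize:
        lo, hi = raw.min(), raw.max()
        out["ac"] = (raw - lo) / (hi - lo) if hi > lo else np.zeros_like(raw)
    else:
        out["ac"] = raw
    for dim in ("social", "physical", "natural", "human", "financial"):
        members = [c for c in cols if INDICATOR_DIMENSIONS.get(c) == dim]
        if members:
            out[f"dim_{dim}"] = scaled[members].mean(axis=1)
    return out


def capacity_scores(indicators: pd.DataFrame,
                    directions: dict[str, str] | None = None,
                    weights=None, normalize: bool = True) -> pd.DataFrame:
    """Full composite: scale every indicator, then aggregate.

    Returns region_id, the 15 ``ac_<indicator>`` columns, the five
    dimension means and the final ``ac`` score.
    """
    directions = directions or DEFAULT_DIRECTIONS
    scaled = pd.DataFrame({"region_id": indicators["region_id"]})
    for col in INDICATOR_COLUMNS:
        scaled[col] = percentile_scale(indicators[col].to_numpy(),
                                       directions.get(col, "higher_is_better"))
    agg = aggregate_capacity(scaled, weights=weights, normalize=normalize)
    out = scaled.rename(columns={c: f"ac_{c}" for c in INDICATOR_COLUMNS})
    return out.merge(agg, on="region_id")


def _validate_pairwise(a: np.ndarray) -> None:
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("pairwise matrix must be square")
    if np.any(a <= 0):
        raise ValueError("pairwise matrix entries must be positive")
    if not np.allclose(a * a.T, 1.0, rtol=1e-8):
        raise ValueError("pairwise matrix is not reciprocal (a_ji != 1/a_ij)")


def ahp_weights(matrix) -> tuple[np.ndarray, float, float]:
    """Principal-eigenvector weights of a pairwise-comparison matrix.

    Power iteration to 1e-10; returns (weights summing to 1, the principal
    eigenvalue lambda_max, and the consistency ratio
    CR = ((lambda_max − n)/(n − 1)) / RI(n)). A perfectly consistent
    matrix (a_ij = w_i/w_j) has lambda_max = n and CR = 0.
    """
    a = np.asarray(getattr(matrix, "values", matrix), dtype=float)
    _validate_pairwise(a)
    n = a.shape[0]
    if n > len(SAATY_RI):
        raise ValueError(f"no random-consistency index for n={n}")
    v = np.full(n, 1.0 / n)
    for _ in range(10_000):
        nv = a @ v
        nv /= nv.sum()
        if np.max(np.abs(nv - v)) < 1e-10:
            v = nv
            break
        v = nv
    lam = float((a @ v / v).mean())
    if n <= 2:
        cr = 0.0
    else:
        ci = (lam - n) / (n - 1)
        cr = float(ci / SAATY_RI[n - 1])
    return v, lam, cr


def check_consistency(cr: float, threshold: float = 0.10) -> tuple[bool, str]:
    """Gate an AHP matrix on its consistency ratio (strict CR < threshold)."""
    if cr < 0:
        raise ValueError("consistency ratio cannot be negative")
    if cr < threshold:
        return True, f"accepted: CR={cr:.4f} below the {threshold:.0%} threshold"
    return False, (f"rejected: CR={cr:.4f} is not below the "
                   f"{threshold:.0%} consistency threshold")


def weight_concordance(weight_sets) -> np.ndarray:
    """Pairwise Spearman rank correlation between expert weight vectors."""
    mat = np.asarray(weight_sets, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("need at least 2 weight sets of equal length")
    k = mat.shape[0]
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            rho = stats.spearmanr(mat[i], mat[j]).statistic
            out[i, j] = out[j, i] = rho
    return out
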