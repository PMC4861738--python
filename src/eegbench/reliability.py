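"""Test-retest agreement (ICC) and effect sizes.

The ICC implemented is the single-measure, absolute-agreement form of the
two-way model (McGraw & Wong's ICC(A,1)), computed from the closed-form
mean-squares decomposition. The consistency form ICC(C,1) is available for
comparison. Undefined statistics are reported as NaN, never raised.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "icc_a1",
    "icc_c1",
    "cohens_d",
    "classify_icc",
    "anova_mean_squares",
]


def _validate(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise ValueError("ICC input must be subjects x sessions")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 sessions, got {n}x{k}")
    if not np.isfinite(data).all():
        raise ValueError("ICC input contains missing/non-finite cells")
    return data


def anova_mean_squares(data: np.ndarray) -> tuple[float, float, float]:
    """Two-way (subjects x sessions, one observation per cell) mean squares.

    Returns (MS_rows, MS_cols, MS_error) with (n-1), (k-1) and
    (n-1)(k-1) degrees of freedom respectively.
    """
    data = _validate(data)
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((data - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    return (
        ss_rows / (n - 1),
        ss_cols / (k - 1),
        ss_err / ((n - 1) * (k - 1)),
    )


def icc_a1(data: np.ndarray) -> float:
    """Single-measure absolute-agreement intraclass correlation.

    (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE)). Returns NaN when the
    table has zero total variance.
    """
    data = _validate(data)
    n, k = data.shape
    msr, msc, mse = anova_mean_squares(data)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        return float("nan")
    return (msr - mse) / denom


def icc_c1(data: np.ndarray) -> float:
    """Single-measure consistency intraclass correlation:
    (MSR - MSE) / (MSR + (k-1) MSE)."""
    data = _validate(data)
    _, k = data.shape
    msr, _, mse = anova_mean_squares(data)
    denom = msr + (k - 1) * mse
    if denom == 0:
        return float("nan")
    return (msr - mse) / denom


def cohens_d(x, y) -> float:
    """Standardized mean difference with the pooled-sd denominator
    (n_x + n_y - 2 degrees of freedom). NaN when the pooled sd is zero."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    nx, ny = x.size, y.size
    pooled_var = (
        ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    )
    if pooled_var == 0:
        return float("nan")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def classify_icc(value: float) -> str:
    """poor (< 0.4), moderate ([0.4, 0.7]) or good (> 0.7).

    NaN sentinels classify as ``undefined``; negative estimates are poor.
    """
    if np.isnan(value):
        return "undefined"
    if value < 0.4:
        return "poor"
    if value > 0.7:
        return "good"
    return "moderate"
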