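"""Independent brute-force oracles for the statistics under test.

Everything here is computed from first-principles formulas (plus special
functions for distribution tails), deliberately avoiding the scipy.stats
routines the implementation calls, so the comparisons are a genuine
dual-route check.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy import special


def pearson_r_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with its two-sided t-distribution p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xm, ym = x - x.mean(), y - y.mean()
    r = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    # two-sided tail of Student's t via the regularized incomplete beta
    p = float(special.betainc(df / 2.0, 0.5, df / (df + t * t)))
    return r, p


def bland_altman(ref: np.ndarray, pred: np.ndarray) -> dict[str, float]:
    """Error and agreement measures by direct formula evaluation."""
    ref = np.asarray(ref, float)
    pred = np.asarray(pred, float)
    d = pred - ref
    n = len(d)
    mae = float(sum(abs(v) for v in d) / n)
    rmse = float(np.sqrt(sum(v * v for v in d) / n))
    bias = float(sum(d) / n)
    sd = float(np.sqrt(sum((v - bias) ** 2 for v in d) / n))
    return {
        "mae": mae,
        "rmse": rmse,
        "nrmse": rmse / (max(ref) - min(ref)),
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
    }


def welch_t_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch's unequal-variance t statistic and two-sided p-value."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    va = a.var(ddof=1) / na
    vb = b.var(ddof=1) / nb
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    p = float(special.betainc(df / 2.0, 0.5, df / (df + t * t)))
    return float(t), p


def paired_t_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided paired t-test p-value."""
    d = np.asarray(a, float) - np.asarray(b, float)
    n = len(d)
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    df = n - 1
    return float(special.betainc(df / 2.0, 0.5, df / (df + t * t)))


def wilcoxon_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided Wilcoxon signed-rank p-value by enumerating all
    2^n sign assignments (tie-free data only; practical for n <= 14)."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0.0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_plus = ranks[d > 0].sum()
    total = ranks.sum()
    w_obs = min(w_plus, total - w_plus)
    count = 0
    for signs in product((0.0, 1.0), repeat=n):
        w = float(np.dot(signs, ranks))
        if min(w, total - w) <= w_obs:
            count += 1
    return min(1.0, count / 2.0**n)
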