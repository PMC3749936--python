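"""Independent brute-force oracles shared across the test suite.

Each implementation here deliberately avoids the code paths it checks:
explicit per-base sets instead of interval arithmetic, explicit matrix
algebra instead of closed-form sums, exhaustive enumeration instead of
library tests.
"""

import math

import numpy as np


def per_base_union(intervals, pad=0):
    """Set of bases covered by the padded intervals."""
    bases = set()
    for s, e in intervals:
        bases.update(range(s - pad, e + pad))
    return bases


def hat_matrix_ols(x, y):
    """OLS of y on [1, x] via explicit normal equations and hat matrix.

    Returns (intercept, slope, residual_std, leverages, residuals,
    internally studentized residuals)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    H = X @ xtx_inv @ X.T
    resid = y - X @ beta
    s = math.sqrt(float(resid @ resid) / (len(x) - 2))
    h = np.diag(H)
    student = resid / (s * np.sqrt(1 - h))
    return float(beta[0]), float(beta[1]), s, h, resid, student


def auc_pair_counting(member_scores, background_scores, lower_predicts_member=True):
    """AUC by exhaustive pair comparison, ties at half weight."""
    total = 0.0
    for m in member_scores:
        for b in background_scores:
            better = m < b if lower_predicts_member else m > b
            total += 1.0 if better else (0.5 if m == b else 0.0)
    return total / (len(member_scores) * len(background_scores))


def mwu_u_enumeration(x, y):
    """U statistic of sample x by direct pair counting (ties half)."""
    return sum(1.0 if a > b else (0.5 if a == b else 0.0) for a in x for b in y)


def binomial_two_tailed(k, n, p0):
    """Two-tailed exact binomial p: sum of P(outcome) <= P(k)."""
    pk = math.comb(n, k) * p0**k * (1 - p0) ** (n - k)
    total = 0.0
    for j in range(n + 1):
        pj = math.comb(n, j) * p0**j * (1 - p0) ** (n - j)
        if pj <= pk * (1 + 1e-12):
            total += pj
    return min(1.0, total)


def fisher_two_tailed(table):
    """Two-tailed Fisher exact p by enumerating the hypergeometric tail."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(k):
        return (
            math.comb(col1, k)
            * math.comb(n - col1, row1 - k)
            / math.comb(n, row1)
        )

    lo = max(0, row1 - (n - col1))
    hi = min(row1, col1)
    p_obs = prob(a)
    return min(1.0, sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-12)))


def logistic_irls(x, y, n_iter=200, tol=1e-12):
    """Logistic regression of y on [1, x] by hand-coded IRLS."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(n_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        z = eta + (y - mu) / w
        wX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ wX, X.T @ (w * z))
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    return beta


def ecdf_percentile(all_scores, value):
    """Empirical-CDF percentile of a value within a score distribution."""
    all_scores = np.asarray(all_scores, dtype=float)
    return 100.0 * np.mean(all_scores <= value)
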