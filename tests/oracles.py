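"""Independent brute-force oracles used to validate the statistics stack.

These are deliberately naive transcriptions of the published formulas and
textbook estimators, kept free of any code shared with the package, so a
test comparing the two routes is a genuine dual implementation.
"""

import numpy as np
from scipy import stats


def ols_normal_equations(X, y):
    """OLS via explicit (X'X)^-1 X'y; returns (beta, rss, df_resid)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    beta = np.linalg.inv(X.T @ X) @ X.T @ y
    resid = y - X @ beta
    return beta, float(resid @ resid), len(y) - X.shape[1]


def f_test_from_rss(rss_r, df_r, rss_f, df_f):
    F = ((rss_r - rss_f) / (df_r - df_f)) / (rss_f / df_f)
    return F, float(stats.f.sf(F, df_r - df_f, df_f))


def welch_anova_oracle(groups):
    """Direct transcription of Welch's heteroscedastic ANOVA formula."""
    k = len(groups)
    n = [len(g) for g in groups]
    xbar = [np.mean(g) for g in groups]
    s2 = [np.var(g, ddof=1) for g in groups]
    w = [n[i] / s2[i] for i in range(k)]
    W = sum(w)
    xw = sum(w[i] * xbar[i] for i in range(k)) / W
    numerator = sum(w[i] * (xbar[i] - xw) ** 2 for i in range(k)) / (k - 1)
    s = sum((1 - w[i] / W) ** 2 / (n[i] - 1) for i in range(k))
    denominator = 1 + 2 * (k - 2) / (k**2 - 1) * s
    F = numerator / denominator
    df1 = k - 1
    df2 = (k**2 - 1) / (3 * s)
    return F, df1, df2, float(stats.f.sf(F, df1, df2))


def games_howell_oracle(groups):
    """Pairwise Games-Howell p-values via the studentized-range distribution."""
    k = len(groups)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = np.asarray(groups[i]), np.asarray(groups[j])
            na, nb = len(a), len(b)
            va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
            se2 = va / na + vb / nb
            t = abs(np.mean(a) - np.mean(b)) / np.sqrt(se2)
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
            p = stats.studentized_range.sf(t * np.sqrt(2), k, df)
            out.append((t, df, float(min(p, 1.0))))
    return out


def bh_stepup_bruteforce(pvals, alpha):
    """Benjamini-Hochberg rejection set by literal step-up enumeration."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * alpha / m:
            k_star = k
    reject = np.zeros(m, bool)
    reject[order[:k_star]] = True
    return reject


def welch_t_test(a, b):
    """Two-sided Welch t-test: (t, df, p)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    se2 = va / len(a) + vb / len(b)
    t = (np.mean(a) - np.mean(b)) / np.sqrt(se2)
    df = se2**2 / (
        (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
    )
    return t, df, float(2 * stats.t.sf(abs(t), df))
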