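"""Independent reference implementations used only to cross-check the package.

These deliberately avoid the code paths they validate: OLS by explicit normal
equations, lobe strengths by per-pair enumeration, mediation z by literal
arithmetic.
"""

import numpy as np
from scipy import stats as sps


def ols_normal_equations(y, X):
    """OLS with intercept via the normal equations.

    Returns (beta, se, t, p) for the non-intercept columns, with the
    conventional t-distribution p-values on n - k - 1 degrees of freedom.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n = y.size
    D = np.column_stack([np.ones(n), X])
    xtx_inv = np.linalg.inv(D.T @ D)
    beta = xtx_inv @ D.T @ y
    resid = y - D @ beta
    df = n - D.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    t = beta / se
    p = 2 * sps.t.sf(np.abs(t), df)
    return beta[1:], se[1:], t[1:], p[1:]


def zscore(x):
    x = np.asarray(x, float)
    return (x - x.mean()) / x.std(ddof=1)


def lobe_strength_bruteforce(weights, atlas, lobe_a, lobe_b):
    """Mean over explicitly enumerated region pairs."""
    ia = [r.index for r in atlas.regions_in_lobe(lobe_a)]
    ib = [r.index for r in atlas.regions_in_lobe(lobe_b)]
    vals = []
    for i in ia:
        for j in ib:
            if i != j:
                vals.append(weights[i, j])
    return float(np.mean(vals))


def region_to_lobe_bruteforce(weights, atlas, region_name, lobe_b):
    sources = [r.index for r in atlas.regions if r.name == region_name]
    ib = [r.index for r in atlas.regions_in_lobe(lobe_b)]
    vals = [weights[i, j] for i in sources for j in ib if i != j]
    return float(np.mean(vals))


def sobel_z_arithmetic(a, se_a, b, se_b):
    return a * b / np.sqrt(b**2 * se_a**2 + a**2 * se_b**2)
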