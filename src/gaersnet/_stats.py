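"""Small shared statistical primitives.

Kept in-package because the NBS permutation loop applies Benjamini-Hochberg
to every permuted edge-wise p-vector; the implementation is a plain
vectorized step-up, cross-checked in the test suite against statsmodels and
hand enumeration.
"""
from __future__ import annotations

import numpy as np


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Parameters
    ----------
    pvalues : 1-D array of raw p-values.

    Returns
    -------
    Array of the same shape with BH-adjusted p-values (monotone, capped at 1).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank downward
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def pooled_t_twosample(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Homoscedastic (pooled-variance) two-sample t, vectorized over columns.

    ``a`` is (n_a, E), ``b`` is (n_b, E). Returns (t, p) arrays of length E,
    two-sided p from the t distribution with n_a + n_b - 2 df. Columns with
    zero pooled variance get t = 0, p = 1.
    """
    from scipy import stats

    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 observations per group")
    df = na + nb - 2
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    ssa = ((a - ma) ** 2).sum(axis=0)
    ssb = ((b - mb) ** 2).sum(axis=0)
    sp2 = (ssa + ssb) / df
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (ma - mb) / np.where(denom > 0, denom, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[denom == 0] = 1.0
    return t, p
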