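"""Functional-connectivity matrices.

Pairwise Pearson correlation between regional time courses, with the
study's conventions baked in: only positive correlations are kept (negative
entries zeroed at construction), matrices are averaged in the Fisher-z
domain, and edge-wise significance is assessed with a two-sided t transform
of r under Benjamini-Hochberg FDR control across all unique edges of the
matrix (2556 edges for 72 regions).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from ._stats import bh_adjust
from .preprocess import RoiTimeSeries

__all__ = [
    "ConnectivityMatrix",
    "correlation_matrix",
    "fisher_average",
    "fdr_significance_mask",
]

_Z_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric R x R weighted connectivity matrix.

    ``domain`` is ``"r"`` (correlation) or ``"z"`` (Fisher).  The diagonal
    is zeroed and excluded from all statistics.  In the r domain every
    retained off-diagonal value lies in [0, 1]; negatives are zeroed before
    construction.  ``flagged_regions`` lists regions whose series were
    constant (their edges are zero).
    """

    weights: np.ndarray
    labels: tuple[str, ...]
    domain: str = "r"
    n_timepoints: Optional[int] = None
    flagged_regions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        labels = tuple(self.labels)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if w.shape[0] != len(labels):
            raise ValueError("label count must match matrix size")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if self.domain not in ("r", "z"):
            raise ValueError("domain must be 'r' or 'z'")
        if not np.isfinite(w).all():
            raise ValueError("weights must be finite")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "flagged_regions", tuple(self.flagged_regions))

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def edge_values(self, nonzero: bool = False) -> np.ndarray:
        """Unique off-diagonal edge values (upper triangle, row-major)."""
        iu = np.triu_indices(self.n_regions, k=1)
        vals = self.weights[iu]
        return vals[vals != 0] if nonzero else vals

    def to_z(self) -> "ConnectivityMatrix":
        if self.domain == "z":
            return self
        r = np.clip(self.weights, -_Z_CLIP, _Z_CLIP)
        z = np.arctanh(r)
        np.fill_diagonal(z, 0.0)
        return replace(self, weights=z, domain="z")

    def to_r(self) -> "ConnectivityMatrix":
        if self.domain == "r":
            return self
        return replace(self, weights=np.tanh(self.weights), domain="r")


def correlation_matrix(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Positive-only Pearson correlation matrix of a regional run.

    Entry (i, j) is the Pearson r of regions i and j when positive, else 0.
    Constant regional series (zero variance) produce zero edges and are
    flagged rather than NaN-propagated.
    """
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 time points for correlation")
    x = ts.values
    sd = x.std(axis=0)
    flagged = [lab for lab, s in zip(ts.labels, sd) if s == 0]
    if flagged:
        warnings.warn(f"constant series zeroed for regions: {flagged}")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    r[r < 0] = 0.0
    np.fill_diagonal(r, 0.0)
    r = (r + r.T) / 2.0
    return ConnectivityMatrix(
        weights=r,
        labels=ts.labels,
        domain="r",
        n_timepoints=ts.n_timepoints,
        flagged_regions=tuple(flagged),
    )


def fisher_average(matrices: Sequence[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Average r-domain matrices edge-wise through the Fisher z transform.

    Per edge: z = atanh(r), arithmetic mean across matrices, back-transform
    tanh.  Zero edges participate as z = 0.  Off-diagonal r = 1 (identical
    series) is clipped to 1 - 1e-7 with a warning.
    """
    if len(matrices) == 0:
        raise ValueError("need at least one matrix")
    labels = matrices[0].labels
    for m in matrices:
        if m.labels != labels:
            raise ValueError("all matrices must share identical region labels")
        if m.domain != "r":
            raise ValueError("fisher_average expects r-domain matrices")
    stack = np.stack([m.weights for m in matrices])
    if (stack < 0).any():
        raise ValueError("r-domain matrices must be positive-only")
    if (stack >= 1.0).any():
        warnings.warn("off-diagonal r >= 1 encountered; clipping to 1 - 1e-7")
        stack = np.clip(stack, 0.0, _Z_CLIP)
    z = np.arctanh(stack)
    avg = np.tanh(z.mean(axis=0))
    nts = [m.n_timepoints for m in matrices if m.n_timepoints is not None]
    n_tp = int(round(float(np.mean(nts)))) if nts else None
    return ConnectivityMatrix(weights=avg, labels=labels, domain="r", n_timepoints=n_tp)


def fdr_significance_mask(
    matrix: ConnectivityMatrix,
    n_timepoints: Optional[int] = None,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """BH-FDR edge significance of an r-domain matrix.

    Per unique off-diagonal edge, p comes from the two-sided t transform of
    r with n - 2 degrees of freedom (``t = r sqrt((n-2)/(1-r^2))``); the BH
    step-up runs across all R(R-1)/2 edges.  Returns (mask, p_matrix): a
    symmetric boolean mask of edges with adjusted p < alpha and the
    symmetric matrix of raw p-values.
    """
    if matrix.domain != "r":
        raise ValueError("significance mask expects an r-domain matrix")
    n = n_timepoints if n_timepoints is not None else matrix.n_timepoints
    if n is None or n <= 3:
        raise ValueError("n_timepoints must exceed 3")
    R = matrix.n_regions
    iu = np.triu_indices(R, k=1)
    r = np.clip(matrix.weights[iu], -_Z_CLIP, _Z_CLIP)
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    adj = bh_adjust(p)
    mask_flat = adj < alpha
    mask = np.zeros((R, R), dtype=bool)
    mask[iu] = mask_flat
    mask |= mask.T
    pmat = np.ones((R, R))
    pmat[iu] = p
    pmat = np.minimum(pmat, pmat.T)
    np.fill_diagonal(pmat, 1.0)
    return mask, pmat
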