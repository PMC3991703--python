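"""Spatial eigenfunction analysis and variation partitioning.

PCNM (principal coordinates of neighbour matrices) eigenfunctions are Moran
eigenvector maps built from a truncated geographic distance matrix: distances
beyond the truncation threshold (by default the longest edge of the minimum
spanning tree, which keeps the sample graph connected) are replaced by four
times the threshold, the matrix is Gower-centered and eigen-decomposed, and
the leading eigenvectors describe broad- to fine-scale spatial patterns.
Community variation is then partitioned, via redundancy-analysis adjusted
R-squared, into pure environmental (a), spatially structured environmental
(b), pure spatial (c) and residual (d) fractions with a + b + c + d = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "PCNMBasis",
    "VariationPartition",
    "pcnm",
    "rda_r2",
    "forward_select",
    "varpart",
]


# ---------------------------------------------------------------------------
# PCNM basis
# ---------------------------------------------------------------------------

@dataclass
class PCNMBasis:
    """Retained spatial eigenfunctions, broadest scale first."""

    eigenvalues: np.ndarray  # descending, > tol * max
    vectors: np.ndarray  # samples x m, columns scaled by sqrt(eigenvalue)
    truncation: float


def pcnm(coords, truncation: float | None = None, rel_tol: float = 1e-8) -> PCNMBasis:
    """Spatial eigenfunctions from a truncated Euclidean distance matrix.

    ``truncation`` defaults to the longest minimum-spanning-tree edge.
    Duplicate coordinates (e.g. two root systems sampled in one quadrat) are
    separated by a deterministic jitter of 1e-6 of the threshold, with a
    warning.  Eigenvectors with eigenvalue > rel_tol * max eigenvalue are
    retained and scaled by the square root of their eigenvalue.
    """
    x = np.asarray(coords, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least three samples with coordinates")
    d = squareform(pdist(x))

    def mst_threshold(dist: np.ndarray) -> float:
        mst = minimum_spanning_tree(dist).toarray()
        return float(mst.max())

    # handle coincident points before computing the final threshold
    dup_mask = (d + np.eye(n)) == 0
    if dup_mask.any():
        uniq = np.unique(x, axis=0)
        if uniq.shape[0] < 3:
            raise ValueError("fewer than three distinct coordinates")
        t0 = truncation if truncation is not None else mst_threshold(
            squareform(pdist(uniq))
        )
        warnings.warn("duplicate coordinates jittered for PCNM", stacklevel=2)
        x = x.copy()
        seen: dict[tuple, int] = {}
        for i in range(n):
            key = tuple(np.round(x[i], 12))
            k = seen.get(key, 0)
            seen[key] = k + 1
            if k:
                x[i, 0] += k * 1e-6 * t0
        d = squareform(pdist(x))

    t = float(truncation) if truncation is not None else mst_threshold(d)
    if t <= 0:
        raise ValueError("non-positive truncation threshold")
    dt = d.copy()
    dt[dt > t] = 4.0 * t
    a = -0.5 * dt**2
    a -= a.mean(axis=0)
    a -= a.mean(axis=1)[:, None]
    a = (a + a.T) / 2.0
    w, v = np.linalg.eigh(a)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    keep = w > rel_tol * w.max()
    w, v = w[keep], v[:, keep]
    return PCNMBasis(eigenvalues=w, vectors=v * np.sqrt(w), truncation=t)


# ---------------------------------------------------------------------------
# Redundancy-analysis R2
# ---------------------------------------------------------------------------

def _drop_aliased(x: np.ndarray) -> np.ndarray:
    """Keep a maximal linearly independent column subset (pivoted QR)."""
    from scipy.linalg import qr

    if x.shape[1] == 0:
        return x
    _, r, piv = qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int((diag > 1e-10 * max(diag[0], 1e-300)).sum()) if diag.size else 0
    if rank < x.shape[1]:
        warnings.warn("dropping aliased predictor columns", stacklevel=3)
    keep = np.sort(piv[:rank])
    return x[:, keep]


def rda_r2(y, x) -> tuple[float, float]:
    """R2 and adjusted R2 of a multivariate linear fit of Y on X.

    Y and X are centered internally; R2 = trace of fitted sums of squares
    over trace of total sums of squares, and
    adjR2 = 1 - (1 - R2)(n - 1)/(n - p - 1) with p the rank of X.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if y.ndim == 1:
        y = y[:, None]
    n = y.shape[0]
    yc = y - y.mean(axis=0)
    xc = x - x.mean(axis=0)
    xc = _drop_aliased(xc)
    p = xc.shape[1]
    if p == 0:
        return 0.0, 0.0
    if n <= p + 1:
        raise ValueError("need n > p + 1 samples")
    q, _ = np.linalg.qr(xc)
    fitted = q @ (q.T @ yc)
    sst = float((yc**2).sum())
    if sst == 0:
        raise ValueError("response matrix has zero variance")
    r2 = float((fitted**2).sum() / sst)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return r2, adj


# ---------------------------------------------------------------------------
# Forward selection of spatial predictors
# ---------------------------------------------------------------------------

def forward_select(y, x_candidates, n_perm: int = 999, alpha: float = 0.05,
                   seed=None, global_stop: bool = True) -> list[int]:
    """Greedy forward selection of predictor columns with permutation tests.

    At each step the candidate adding the most R2 is tested with a
    permutation F test (rows of Y permuted); entry requires P <= alpha.
    ``global_stop`` applies the double-stopping safeguard: selection only
    begins if the full candidate model is itself significant at alpha
    (otherwise picking the best of many noise candidates inflates type-I
    error far above alpha), and it ends once the cumulative adjusted R2
    exceeds that of the full model.  Returns the selected column indices in
    order of entry; may be empty.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    x = np.asarray(x_candidates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, m = x.shape
    if m == 0:
        return []
    yc = y - y.mean(axis=0)
    sst = float((yc**2).sum())

    def r2_of(cols: list[int], yy: np.ndarray) -> float:
        xc = x[:, cols] - x[:, cols].mean(axis=0)
        q, _ = np.linalg.qr(xc)
        fitted = q @ (q.T @ yy)
        return float((fitted**2).sum() / sst)

    global_adj = np.inf
    if global_stop:
        # gatekeeper: test the all-candidates model before any selection
        r2_glob, global_adj = rda_r2(yc, x)
        p_glob = _drop_aliased(x - x.mean(axis=0)).shape[1]
        if n - p_glob - 1 <= 0:
            raise ValueError("too few samples for the global test")
        f_glob = (r2_glob / p_glob) / ((1 - r2_glob) / (n - p_glob - 1))
        all_cols = list(range(m))
        exceed_glob = 0
        for _ in range(n_perm):
            yp = yc[rng.permutation(n)]
            r2p = r2_of(all_cols, yp)
            exceed_glob += (r2p / p_glob) / ((1 - r2p) / (n - p_glob - 1)) >= f_glob - 1e-12
        if (1 + exceed_glob) / (n_perm + 1) > alpha:
            return []

    selected: list[int] = []
    remaining = list(range(m))
    r2_old = 0.0
    while remaining:
        gains = [(r2_of(selected + [j], yc), j) for j in remaining]
        r2_new, jbest = max(gains)
        p_model = len(selected) + 1
        if n - p_model - 1 <= 0 or r2_new >= 1 - 1e-12:
            break
        fstat = (r2_new - r2_old) / ((1 - r2_new) / (n - p_model - 1))
        exceed = 0
        cols = selected + [jbest]
        for _ in range(n_perm):
            yp = yc[rng.permutation(n)]
            r2p_new = r2_of(cols, yp)
            r2p_old = r2_of(selected, yp) if selected else 0.0
            fp = (r2p_new - r2p_old) / ((1 - r2p_new) / (n - p_model - 1))
            exceed += fp >= fstat - 1e-12
        pval = (1 + exceed) / (n_perm + 1)
        if pval > alpha:
            break
        selected.append(jbest)
        remaining.remove(jbest)
        r2_old = r2_new
        if global_stop and rda_r2(yc, x[:, selected])[1] > global_adj:
            break
    return selected


# ---------------------------------------------------------------------------
# Variation partitioning
# ---------------------------------------------------------------------------

@dataclass
class VariationPartition:
    """Adjusted-R2 decomposition of community variation.

    a: pure environment, b: spatially structured environment, c: pure
    space, d: residual; a + b + c + d = 1 by construction (individual
    fractions may be negative, as is standard for adjusted R2).
    """

    adjR2_env: float  # a + b
    adjR2_spa: float  # b + c
    adjR2_joint: float  # a + b + c
    a: float = field(init=False)
    b: float = field(init=False)
    c: float = field(init=False)
    d: float = field(init=False)

    def __post_init__(self) -> None:
        self.a = self.adjR2_joint - self.adjR2_spa
        self.c = self.adjR2_joint - self.adjR2_env
        self.b = self.adjR2_env + self.adjR2_spa - self.adjR2_joint
        self.d = 1.0 - self.adjR2_joint

    def as_dict(self) -> dict[str, float]:
        return {
            "adjR2_env": self.adjR2_env,
            "adjR2_spa": self.adjR2_spa,
            "adjR2_joint": self.adjR2_joint,
            "a": self.a, "b": self.b, "c": self.c, "d": self.d,
        }


def varpart(y, env, spatial) -> VariationPartition:
    """Partition variation of Y between environmental and spatial predictors.

    Y is typically the Hellinger-transformed community matrix; ``spatial``
    the forward-selected PCNM eigenfunctions.  Fractions come from the three
    adjusted R2 values of Y on Env, on Spatial, and on their union.
    """
    env = np.asarray(env, dtype=float)
    spatial = np.asarray(spatial, dtype=float)
    if env.ndim == 1:
        env = env[:, None]
    if spatial.ndim == 1:
        spatial = spatial[:, None]
    _, ab = rda_r2(y, env)
    _, bc = rda_r2(y, spatial)
    _, abc = rda_r2(y, np.hstack([env, spatial]))
    return VariationPartition(adjR2_env=ab, adjR2_spa=bc, adjR2_joint=abc)
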