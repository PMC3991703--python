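"""Ordination and permutation statistics: NMDS, envfit, Mantel and IndVal.

Non-metric multidimensional scaling embeds samples in k dimensions so that
the rank order of configuration distances matches the rank order of the
observed dissimilarities, minimizing Kruskal stress-1

    stress = sqrt( sum (d - dhat)^2 / sum d^2 )

where dhat is the monotone (isotonic) regression of configuration distances
on the dissimilarities.  Environmental vectors are fitted post hoc by least
squares onto the ordination scores; Mantel tests correlate two distance
matrices; IndVal scores species as indicators of sample groups.  All
permutation P values use the (1 + exceedances) / (n_perm + 1) estimator, so
they are never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .data_model import CommunityTable, DistanceMatrix, EnvTable

__all__ = [
    "OrdinationResult",
    "EnvFitResult",
    "MantelResult",
    "IndValResult",
    "nmds",
    "envfit",
    "mantel",
    "indval",
]


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """NMDS configuration: centered scores rotated to principal axes."""

    scores: np.ndarray  # samples x k
    stress: float  # Kruskal stress-1 of the best restart
    n_restarts: int
    converged: bool
    stress_trace: np.ndarray  # per-iteration stress of the winning restart
    sample_ids: list | None = None


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float((d**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def _smacof_run(delta: np.ndarray, order: np.ndarray, x0: np.ndarray,
                max_iter: int, tol: float) -> tuple[np.ndarray, float, np.ndarray, bool]:
    """One majorization run from a start configuration.

    Alternates isotonic regression of configuration distances on the
    dissimilarities (primary tie approach: ties pre-sorted by distance) with
    a Guttman transform toward the fitted disparities.
    """
    n = x0.shape[0]
    x = x0 - x0.mean(axis=0)
    trace = []
    prev = np.inf
    converged = False
    n_d = delta.size
    for _ in range(max_iter):
        d = pdist(x)
        if (d == 0).any():
            d = d + 1e-12
        # ties in delta: order within a tie block by current distance, which
        # lets the monotone fit hug the data (primary approach)
        o = order[np.argsort(d[order], kind="stable")]
        o = o[np.argsort(delta[o], kind="stable")]
        dhat = np.empty_like(d)
        dhat[o] = isotonic_regression(d[o]).x
        s = _stress1(d, dhat)
        trace.append(s)
        if prev - s < tol:
            converged = prev - s > -tol  # stopped by tolerance, not divergence
            break
        prev = s
        # normalize disparities to the scale of the distances, then Guttman
        scale = np.sqrt((d**2).sum() / max((dhat**2).sum(), 1e-300))
        dh = dhat * scale
        ratio = squareform(dh / d, checks=False)
        b = -ratio
        np.fill_diagonal(b, ratio.sum(axis=1))
        x = (b @ x) / n
        x -= x.mean(axis=0)
    return x, trace[-1], np.asarray(trace), converged


def nmds(dm: DistanceMatrix, k: int = 2, restarts: int = 20, max_iter: int = 500,
         tol: float = 1e-7, seed=None) -> OrdinationResult:
    """Non-metric MDS of a distance matrix into k dimensions.

    Runs one start from the metric (principal-coordinate) configuration plus
    ``restarts - 1`` seeded random starts, and keeps the lowest-stress
    solution; the returned configuration is centered and rotated to its
    principal axes.
    """
    n = len(dm.ids)
    if n < k + 1:
        raise ValueError("need at least k+1 samples")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    delta = dm.condensed()
    order = np.argsort(delta, kind="stable")

    # metric start: principal coordinates of the (possibly non-Euclidean) matrix
    a = -0.5 * dm.d**2
    a -= a.mean(axis=0)
    a -= a.mean(axis=1)[:, None]
    w, v = np.linalg.eigh(a)
    idx = np.argsort(w)[::-1][:k]
    pcoa = v[:, idx] * np.sqrt(np.clip(w[idx], 0, None))

    best = None
    for r in range(max(1, restarts)):
        x0 = pcoa if r == 0 else rng.standard_normal((n, k))
        if np.allclose(x0, 0):
            x0 = rng.standard_normal((n, k))
        x, s, trace, conv = _smacof_run(delta, order, x0, max_iter, tol)
        if best is None or s < best[1]:
            best = (x, s, trace, conv)
    x, s, trace, conv = best
    # rotate to principal axes
    x = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    return OrdinationResult(
        scores=x, stress=s, n_restarts=max(1, restarts), converged=conv,
        stress_trace=trace, sample_ids=list(dm.ids),
    )


# ---------------------------------------------------------------------------
# envfit
# ---------------------------------------------------------------------------

@dataclass
class EnvFitResult:
    """Fitted environmental vectors: per-variable direction, r2, permutation P."""

    table: pd.DataFrame  # columns: r2, P, plus one direction cosine per axis


def envfit(ordination: OrdinationResult, env: EnvTable, n_perm: int = 999,
           seed=None) -> EnvFitResult:
    """Least-squares fit of each environment variable onto ordination scores.

    r2 is the coefficient of determination of the variable regressed on the
    (centered) scores; the direction is the unit vector of regression
    coefficients; P permutes the variable's values across samples.  Constant
    variables are flagged with NaN r2.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x = ordination.scores - ordination.scores.mean(axis=0)
    if ordination.sample_ids is not None:
        env = env.aligned_to(ordination.sample_ids)
    q, _ = np.linalg.qr(x)
    k = x.shape[1]
    rows = {}
    for name in env.variables:
        v = env.table[name].to_numpy(dtype=float)
        v = v - v.mean()
        sst = float(v @ v)
        if sst <= 0:
            rows[name] = [np.nan, np.nan] + [np.nan] * k
            continue
        coef, *_ = np.linalg.lstsq(x, v, rcond=None)
        norm = np.linalg.norm(coef)
        direction = coef / norm if norm > 0 else coef
        proj = q.T @ v
        r2 = float(proj @ proj / sst)
        perms = np.empty(n_perm)
        for b in range(n_perm):
            vp = v[rng.permutation(v.size)]
            pp = q.T @ vp
            perms[b] = pp @ pp / sst
        p = float((1 + (perms >= r2 - 1e-12).sum()) / (n_perm + 1))
        rows[name] = [r2, p] + direction.tolist()
    cols = ["r2", "P"] + [f"axis{i + 1}" for i in range(k)]
    return EnvFitResult(pd.DataFrame.from_dict(rows, orient="index", columns=cols))


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    P: float
    n_perm: int


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999,
           seed=None) -> MantelResult:
    """Mantel correlation between two distance matrices over the same samples.

    Pearson r over the lower-triangle entries; the one-tailed P value
    permutes rows and columns of the second matrix simultaneously.
    """
    if list(d1.ids) != list(d2.ids):
        raise ValueError("distance matrices must share ids in the same order")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x = d1.condensed()
    y = d2.condensed()
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a distance matrix")
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    r = float(xc @ yc / x.size)
    n = len(d1.ids)
    d2sq = d2.d
    perms = np.empty(n_perm)
    for b in range(n_perm):
        p = rng.permutation(n)
        yp = squareform(d2sq[np.ix_(p, p)], checks=False)
        ypc = (yp - yp.mean()) / yp.std()
        perms[b] = xc @ ypc / x.size
    pval = float((1 + (perms >= r - 1e-12).sum()) / (n_perm + 1))
    return MantelResult(r=r, P=pval, n_perm=n_perm)


# ---------------------------------------------------------------------------
# Indicator species analysis
# ---------------------------------------------------------------------------

@dataclass
class IndValResult:
    """Per-species indicator values with the best group and permutation P."""

    table: pd.DataFrame  # columns: best_group, A, B, indval, P, indicator
    threshold: float


def _indval_stats(vals: np.ndarray, group_codes: np.ndarray, n_groups: int):
    """Best-group IndVal per species for one labeling.

    A (specificity): mean abundance in the group over the summed group means;
    B (fidelity): occupancy fraction within the group; IndVal = A * B,
    maximized over groups.
    """
    n, s = vals.shape
    sums = np.zeros((n_groups, s))
    occ = np.zeros((n_groups, s))
    np.add.at(sums, group_codes, vals)
    np.add.at(occ, group_codes, (vals > 0).astype(float))
    sizes = np.bincount(group_codes, minlength=n_groups).astype(float)
    means = sums / sizes[:, None]
    tot = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(tot > 0, means / np.where(tot > 0, tot, 1.0), 0.0)
    b = occ / sizes[:, None]
    iv = a * b
    best = iv.argmax(axis=0)
    cols = np.arange(s)
    return iv[best, cols], best, a[best, cols], b[best, cols]


def indval(t: CommunityTable, groups, n_perm: int = 999, seed=None,
           threshold: float = 0.6) -> IndValResult:
    """Dufrene-Legendre indicator species analysis.

    ``groups`` maps sample id to group label (mapping or pandas Series).
    Significance permutes group labels across samples (unrestricted).  A
    species is flagged as a strong indicator when IndVal >= ``threshold``
    (0-1 scale) and P <= 0.05.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    g = pd.Series(groups).reindex(t.sample_ids)
    if g.isna().any():
        raise ValueError("group labels missing for some samples")
    labels, codes = np.unique(g.to_numpy(), return_inverse=True)
    if labels.size < 2:
        raise ValueError("need at least two groups")
    vals = t.values()
    iv, best, a, b = _indval_stats(vals, codes, labels.size)
    exceed = np.zeros(vals.shape[1])
    for _ in range(n_perm):
        perm_codes = codes[rng.permutation(codes.size)]
        ivp, *_ = _indval_stats(vals, perm_codes, labels.size)
        exceed += ivp >= iv - 1e-12
    pvals = (1 + exceed) / (n_perm + 1)
    absent = vals.sum(axis=0) == 0
    iv = np.where(absent, 0.0, iv)
    pvals = np.where(absent, 1.0, pvals)
    table = pd.DataFrame(
        {
            "best_group": labels[best],
            "A": a,
            "B": b,
            "indval": iv,
            "P": pvals,
            "indicator": (iv >= threshold) & (pvals <= 0.05),
        },
        index=t.phylotype_ids,
    )
    return IndValResult(table=table, threshold=threshold)
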