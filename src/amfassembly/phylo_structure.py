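"""Phylogenetic community structure: abundance-weighted MNTD and the NTI.

Under trait conservatism, environmental filtering draws co-occurring taxa
from the same clades, so their mean nearest taxon distance (MNTD) falls
below the null expectation (phylogenetic clustering); competitive exclusion
pushes it above (overdispersion).  The nearest taxon index standardizes the
observed MNTD against a null distribution obtained by shuffling taxon labels
on the cophenetic distance matrix:

    NTI = -(MNTD_obs - mean(MNTD_null)) / sd(MNTD_null)

so clustering gives NTI > 0.  Per-patch inference is a one-sample two-tailed
t-test of mean NTI against zero.
"""

from __future__ import annotations

import io
import zlib
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import stats

__all__ = [
    "PhyloDistances",
    "NTIResult",
    "cophenetic_from_newick",
    "mntd_weighted",
    "nti",
    "patch_nti_test",
    "sample_seed",
]


@dataclass
class PhyloDistances:
    """Cophenetic (patristic) distances over a fixed taxon set."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if len(set(self.taxa)) != n:
            raise ValueError("duplicate taxa")
        if d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(d, d.T, atol=1e-10) or not np.allclose(np.diag(d), 0):
            raise ValueError("cophenetic matrix must be symmetric with zero diagonal")
        if (d < 0).any():
            raise ValueError("negative patristic distances")
        self.d = d

    def index_of(self, taxa) -> np.ndarray:
        lookup = {t: i for i, t in enumerate(self.taxa)}
        try:
            return np.array([lookup[t] for t in taxa], dtype=int)
        except KeyError as exc:
            raise KeyError(f"taxon {exc} not in tree") from exc


def cophenetic_from_newick(tree_text: str) -> PhyloDistances:
    """Patristic tip-to-tip distances (sums of branch lengths) from newick."""
    tree = dendropy.Tree.get(data=tree_text, schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and edge.length is None:
            raise ValueError("tree has missing branch lengths")
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return PhyloDistances(labels, d)


def _mntd(d: np.ndarray, idx: np.ndarray, w: np.ndarray) -> float:
    sub = d[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(w @ sub.min(axis=1))


def mntd_weighted(abundance, taxa, pd: PhyloDistances) -> float:
    """Abundance-weighted mean nearest taxon distance of one community.

    Each present taxon contributes its distance to the nearest other present
    taxon, weighted by its relative abundance among present taxa.
    """
    a = np.asarray(abundance, dtype=float)
    if (a < 0).any():
        raise ValueError("negative abundances")
    present = a > 0
    if present.sum() < 2:
        raise ValueError("MNTD undefined with fewer than two present taxa")
    idx = pd.index_of([t for t, p in zip(taxa, present) if p])
    w = a[present] / a[present].sum()
    return _mntd(pd.d, idx, w)


@dataclass
class NTIResult:
    mntd_obs: float
    null_mean: float
    null_sd: float
    nti: float
    n_null: int
    p_quantile: float  # rank position of the observed MNTD within the null
    degenerate: bool = False


def nti(abundance, taxa, pd: PhyloDistances, n_null: int = 999, seed=None) -> NTIResult:
    """Nearest taxon index under the taxa-label-shuffling null model.

    Null communities keep the observed abundance weights but permute taxon
    identities across the full tip pool of the tree (equivalent to shuffling
    the labels of the distance matrix), so neither the distance multiset nor
    the abundances change.  NTI is undefined when the null has zero spread
    (e.g. all pairwise distances equal); such results carry a degenerate
    flag.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a = np.asarray(abundance, dtype=float)
    present = a > 0
    if present.sum() < 2:
        raise ValueError("NTI undefined with fewer than two present taxa")
    idx = pd.index_of([t for t, p in zip(taxa, present) if p])
    w = a[present] / a[present].sum()
    obs = _mntd(pd.d, idx, w)
    n = len(pd.taxa)
    nulls = np.empty(n_null)
    for b in range(n_null):
        perm = rng.permutation(n)
        nulls[b] = _mntd(pd.d, perm[idx], w)
    mu = float(nulls.mean())
    sd = float(nulls.std(ddof=1))
    if sd < 1e-12:
        return NTIResult(obs, mu, sd, float("nan"), n_null, float("nan"), degenerate=True)
    rank = float((1 + (nulls <= obs).sum()) / (n_null + 1))
    return NTIResult(obs, mu, sd, -(obs - mu) / sd, n_null, rank)


def patch_nti_test(nti_values) -> tuple[float, float, float, float]:
    """One-sample two-tailed t-test of mean NTI against zero.

    Returns (mean, SE, t, P).  Requires n >= 2 and nonzero variance.
    """
    v = np.asarray(nti_values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least two NTI values")
    if v.std(ddof=1) == 0:
        raise ValueError("zero variance among NTI values")
    res = stats.ttest_1samp(v, 0.0)
    se = float(v.std(ddof=1) / np.sqrt(v.size))
    return float(v.mean()), se, float(res.statistic), float(res.pvalue)


def sample_seed(master_seed: int, sample_id: str) -> int:
    """Stable per-community seed derived from a master seed and sample id."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(str(sample_id).encode())) % (2**31)
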