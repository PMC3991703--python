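"""Synthetic studies with known generating processes.

Emulates the field design the package analyses: four meadow patches along a
toxic-plant density gradient (Control, LD, MD, HD), five quadrats per patch,
and two root systems per quadrat (the focal plant and its neighbours), with
roughly 34 clones sampled per root sample so pooled communities reach the
J ~ 500-700 range.  Ground truth is explicit: a pure-birth phylogeny; a
trait evolved by Brownian motion on an early-burst clock, so it is strongly
phylogenetically conserved; Gaussian trait filters of known width aimed at
the mean trait of a focal high-trait clade (a tolerance that evolved once),
with the Control patch assembling randomly; per-sample lognormal colonization
lotteries supplying realistic single-phylotype dominance; optional planted
indicator species; and an environment mixing a measured patch-level gradient
with an unmeasured quadrat-scale spatial field.  Every generator is a pure
function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .data_model import CommunityTable, EnvTable
from .neutral_model import simulate_neutral_sad

__all__ = [
    "GeneratorConfig",
    "SyntheticStudy",
    "generate_yule_tree",
    "eb_rescale",
    "evolve_trait_bm",
    "assemble_filtered",
    "assemble_random",
    "generate_study",
]


# ---------------------------------------------------------------------------
# Phylogeny and traits
# ---------------------------------------------------------------------------

def generate_yule_tree(n_tips: int, birth_rate: float = 1.0, seed=None) -> str:
    """Ultrametric pure-birth tree as a newick string, tips Phy-1..Phy-n.

    Lineages split at rate ``birth_rate`` each; a final exponential interval
    at the full rate follows the last split so terminal branches are
    positive.  All tip depths are equal by construction.
    """
    if n_tips < 2:
        raise ValueError("need at least two tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    root = {"birth": 0.0, "children": []}
    active = [root]
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        node = active.pop(int(rng.integers(k)))
        node["children"] = [
            {"birth": t, "children": []},
            {"birth": t, "children": []},
        ]
        active.extend(node["children"])
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    labels = iter(f"Phy-{i + 1}" for i in range(n_tips))

    def write(node) -> str:
        if node["children"]:
            inner = ",".join(write(c) for c in node["children"])
            end = node["children"][0]["birth"]
            return f"({inner}):{end - node['birth']:.10f}"
        return f"{next(labels)}:{t - node['birth']:.10f}"

    # root edge length is written but zero (root born at 0, splits at 0 only
    # if the first event is instantaneous, which it is not) — keep it.
    return write(root) + ";"


def eb_rescale(tree_newick: str, rate: float) -> str:
    """Early-burst rescaling of the trait clock.

    Each edge's length is multiplied by exp(-rate * t_mid / T), where t_mid
    is the edge midpoint's depth and T the tree height.  Trait variance then
    accrues mostly on deep branches, so clades carry near-constant trait
    values — a strong form of phylogenetic niche conservatism.  rate = 0
    leaves the clock (and hence plain Brownian evolution) unchanged.
    """
    if rate == 0:
        return tree_newick
    tree = dendropy.Tree.get(data=tree_newick, schema="newick")
    depth = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
    height = max(depth[id(l)] for l in tree.leaf_node_iter())
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or not node.edge.length:
            continue
        t_mid = (depth[id(node.parent_node)] + depth[id(node)]) / 2.0
        node.edge.length *= math.exp(-rate * t_mid / height)
    return tree.as_string(schema="newick", suppress_rooting=True)


def evolve_trait_bm(tree_newick: str, sigma2: float, seed=None) -> pd.Series:
    """Brownian-motion trait along the tree from a root value of zero.

    Each branch adds a Normal(0, sigma2 * branch length) increment, so the
    trait is phylogenetically conserved: closely related tips get similar
    values and tip variance grows as sigma2 times depth.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    tree = dendropy.Tree.get(data=tree_newick, schema="newick")
    values: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        edge = node.edge.length or 0.0
        parent = values[id(node.parent_node)]
        values[id(node)] = parent + rng.normal(0.0, math.sqrt(sigma2 * edge))
    return pd.Series(
        {leaf.taxon.label: values[id(leaf)] for leaf in tree.leaf_node_iter()}
    )


# ---------------------------------------------------------------------------
# Community assembly
# ---------------------------------------------------------------------------

def assemble_filtered(traits, env_value: float, sigma_w: float, J: int,
                      seed=None, base_abundance=None) -> np.ndarray:
    """One sample assembled under Gaussian environmental filtering.

    Species sampling weights are proportional to
    exp(-(trait - env_value)^2 / (2 sigma_w^2)) times a lognormal base
    abundance; the sample is a multinomial draw of J individuals.  As
    sigma_w grows the filter flattens and assembly becomes random.
    """
    if J < 1:
        raise ValueError("J must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    tr = np.asarray(traits, dtype=float)
    base = (
        rng.lognormal(0.0, 1.0, tr.size)
        if base_abundance is None
        else np.asarray(base_abundance, dtype=float)
    )
    if sigma_w is None or not np.isfinite(sigma_w):
        w = base.copy()
    else:
        if sigma_w <= 0:
            raise ValueError("sigma_w must be > 0")
        w = base * np.exp(-((tr - env_value) ** 2) / (2.0 * sigma_w**2))
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("degenerate filter: all weights zero")
    return rng.multinomial(J, w / total)


def assemble_random(pool_size: int, J: int, seed=None, base_abundance=None) -> np.ndarray:
    """One sample assembled with no trait filter (stochastic null)."""
    if J < 1:
        raise ValueError("J must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    base = (
        rng.lognormal(0.0, 1.0, pool_size)
        if base_abundance is None
        else np.asarray(base_abundance, dtype=float)
    )
    return rng.multinomial(J, base / base.sum())


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------

@dataclass
class GeneratorConfig:
    """Study-level generator settings.

    Defaults mirror the field design: 4 patches x 5 quadrats x 2 root
    systems, 30 phylotypes, ~34 clones per root sample (so per-root-system
    pools land near J = 507/677).  In the filtered patches the Gaussian
    filter is aimed at a focal lineage: the optimum is the mean standardized
    trait of the high-trait clade of 4-8 tips (tolerance of the toxic
    plant's allelochemicals, evolved once), shifted by the per-patch
    ``patch_optima`` offsets; the Control patch has no filter.  Filter
    widths are in standardized-trait SD units.  ``spatial_weight`` adds an
    unmeasured smooth spatial field to the realized optimum, producing a
    pure-spatial variance fraction; set it to zero for environment-only
    studies.
    """

    n_patches: int = 4
    n_quadrats: int = 5
    n_phylotypes: int = 30
    j_sample: int = 34
    theta: float = 9.0
    I: float = 5.0
    birth_rate: float = 1.0
    bm_sigma2: float = 1.0
    eb_rate: float = 8.0  # early-burst trait clock; 0 = plain Brownian
    filter_sigma: tuple = (None, 0.2, 0.2, 0.2)
    patch_optima: tuple = (0.0, 0.0, 0.1, 0.2)  # offsets from the clade mean
    lv_density: tuple = (0.0, 10.0, 40.0, 80.0)
    quadrat_noise: float = 0.1
    env_noise: float = 0.1
    spatial_weight: float = 0.2
    spatial_wavelength: float = 10.0  # microhabitat scale; ~2x quadrat spread
    extent: float = 50.0
    patch_size: float = 5.0
    assembly: str = "filtered"  # or "neutral"
    planted_indicator: bool = False
    planted_patch: str = "HD"
    planted_fraction: float = 0.15
    seed: int = 0

    def patch_names(self) -> list[str]:
        if self.n_patches == 4:
            return ["Control", "LD", "MD", "HD"]
        return [f"P{i + 1}" for i in range(self.n_patches)]


@dataclass
class SyntheticStudy:
    """A complete generated study with its ground truth."""

    community: CommunityTable
    tree: str
    env: EnvTable
    coords: pd.DataFrame
    truth: dict = field(default_factory=dict)


def _spatial_field(x: float, y: float, extent: float) -> float:
    return math.sin(2 * math.pi * x / extent) + math.cos(2 * math.pi * y / extent)


def _focal_clade(tree_newick: str, traits: pd.Series,
                 lo: int = 4, hi: int = 8) -> tuple[float, list[str]]:
    """High-trait clade the filter is aimed at.

    Among subtrees with lo..hi tips, pick the one maximizing
    mean(trait) - 0.5 sd(trait): a lineage that is both high and internally
    coherent, so a filter window centred on its mean admits the whole clade
    and little else.  Returns (clade trait mean, tip labels).
    """
    tree = dendropy.Tree.get(data=tree_newick, schema="newick")
    best = None
    for node in tree.preorder_internal_node_iter():
        tips = [l.taxon.label for l in node.leaf_iter()]
        if lo <= len(tips) <= hi:
            vals = traits.loc[tips].to_numpy()
            score = float(vals.mean() - 0.5 * vals.std())
            if best is None or score > best[0]:
                best = (score, float(vals.mean()), tips)
    if best is None:  # tiny trees: fall back to the top-trait pair
        top = traits.sort_values().index[-2:]
        return float(traits.loc[top].mean()), list(top)
    return best[1], best[2]


def generate_study(config: GeneratorConfig | None = None, **overrides) -> SyntheticStudy:
    """Generate one synthetic study; identical seeds give identical output."""
    cfg = config or GeneratorConfig()
    if overrides:
        cfg = GeneratorConfig(**{**cfg.__dict__, **overrides})
    if len(cfg.filter_sigma) != cfg.n_patches or len(cfg.patch_optima) != cfg.n_patches:
        raise ValueError("filter_sigma and patch_optima must have one entry per patch")
    rng = np.random.default_rng(cfg.seed)
    patches = cfg.patch_names()

    tree = generate_yule_tree(cfg.n_phylotypes, cfg.birth_rate, rng)
    traits_raw = evolve_trait_bm(eb_rescale(tree, cfg.eb_rate), cfg.bm_sigma2, rng)
    phylotypes = list(traits_raw.index)
    traits = (traits_raw - traits_raw.mean()) / max(traits_raw.std(ddof=0), 1e-12)
    tr = traits.to_numpy()
    clade_mean, clade_tips = _focal_clade(tree, traits)

    planted_idx = cfg.n_phylotypes - 1 if cfg.planted_indicator else None

    # patch centers on a square arrangement inside the study extent
    grid = math.ceil(math.sqrt(cfg.n_patches))
    spacing = cfg.extent / grid
    centers = [
        ((i % grid + 0.5) * spacing, (i // grid + 0.5) * spacing)
        for i in range(cfg.n_patches)
    ]

    rows, meta, env_rows = [], [], []
    truth_quadrats = {}
    for p, patch in enumerate(patches):
        sigma_w = cfg.filter_sigma[p]
        mu_p = clade_mean + cfg.patch_optima[p]
        if cfg.assembly == "neutral":
            pooled = {}
            for rs in ("focal", "neighborhood"):
                sad_pool = np.zeros(cfg.n_phylotypes, dtype=int)
                draw = simulate_neutral_sad(
                    cfg.theta, cfg.I, cfg.n_quadrats * cfg.j_sample, rng
                )
                # map simulated species onto phylotype slots (most abundant first)
                k = min(draw.S, cfg.n_phylotypes)
                slots = rng.permutation(cfg.n_phylotypes)[:k]
                sad_pool[slots] = draw.abundances[:k]
                extra = int(draw.abundances[k:].sum())
                if extra:  # rare overflow beyond the pool size: fold into last slot
                    sad_pool[slots[-1]] += extra
                pooled[rs] = sad_pool
        for q in range(cfg.n_quadrats):
            cx, cy = centers[p]
            qx = cx + rng.uniform(-cfg.patch_size / 2, cfg.patch_size / 2)
            qy = cy + rng.uniform(-cfg.patch_size / 2, cfg.patch_size / 2)
            g = _spatial_field(qx, qy, cfg.spatial_wavelength)
            opt_env = mu_p + rng.normal(0.0, cfg.quadrat_noise)
            opt_used = opt_env + cfg.spatial_weight * g
            truth_quadrats[f"{patch}-Q{q + 1}"] = {
                "optimum_env": opt_env, "optimum_used": opt_used, "sigma_w": sigma_w,
            }
            for rs in ("focal", "neighborhood"):
                sid = f"{patch}-Q{q + 1}-{rs}"
                if cfg.assembly == "neutral":
                    # split the pooled urn draw across quadrats without replacement
                    remaining_q = cfg.n_quadrats - q
                    counts = rng.multivariate_hypergeometric(
                        pooled[rs], int(pooled[rs].sum()) // remaining_q
                    )
                    pooled[rs] = pooled[rs] - counts
                else:
                    j_draw = cfg.j_sample
                    # independent lottery per sample: each root sample is its
                    # own colonization history
                    w_base = rng.lognormal(0.0, 1.0, cfg.n_phylotypes)
                    if planted_idx is not None:
                        w_base[planted_idx] = 0.0  # lives only where planted
                    if planted_idx is not None and patch == cfg.planted_patch:
                        n_planted = max(1, round(cfg.planted_fraction * cfg.j_sample))
                        j_draw = cfg.j_sample - n_planted
                    if sigma_w is None:
                        counts = assemble_random(
                            cfg.n_phylotypes, j_draw, rng, base_abundance=w_base
                        )
                    else:
                        counts = assemble_filtered(
                            tr, opt_used, sigma_w, j_draw, rng, base_abundance=w_base
                        )
                    if planted_idx is not None and patch == cfg.planted_patch:
                        counts = counts.copy()
                        counts[planted_idx] = n_planted
                rows.append(counts)
                meta.append(
                    {"sample_id": sid, "patch": patch, "root_system": rs,
                     "x": qx, "y": qy}
                )
                env_rows.append(
                    {
                        "sample_id": sid,
                        "filter_env": opt_env + rng.normal(0.0, cfg.env_noise),
                        "lv_density": cfg.lv_density[p] * (1 + rng.normal(0.0, 0.05)),
                        "soil_ph": rng.normal(6.5, 0.3),
                        "soil_moisture": rng.normal(30.0, 3.0),
                    }
                )

    md = pd.DataFrame(meta).set_index("sample_id")
    ab = pd.DataFrame(
        np.asarray(rows, dtype=float), index=md.index, columns=phylotypes
    )
    env = EnvTable(pd.DataFrame(env_rows).set_index("sample_id").astype(float))
    community = CommunityTable(ab, md)
    truth = {
        "config": {k: v for k, v in cfg.__dict__.items()},
        "traits": dict(zip(phylotypes, tr.tolist())),
        "focal_clade": {"tips": clade_tips, "trait_mean": clade_mean},
        "quadrats": truth_quadrats,
        "planted_indicator": phylotypes[planted_idx] if planted_idx is not None else None,
    }
    return SyntheticStudy(
        community=community,
        tree=tree,
        env=env,
        coords=md[["x", "y"]].copy(),
        truth=truth,
    )
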