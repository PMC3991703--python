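"""End-to-end analysis pipeline producing a machine-readable report.

Runs, in order: data validation and diversity, ordination statistics (NMDS,
envfit, Mantel, IndVal), neutral-model fitting with goodness of fit,
phylogenetic structure (per-sample NTI, per patch x root-system t-tests),
and spatial variation partitioning.  Stages that lack their inputs (no
coordinates, no tree, ...) are skipped with a logged notice; a stage failure
is recorded under its name and the remaining stages still run.  All
randomness flows from a single master seed, so re-running with the same
config and inputs reproduces the report exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import __version__
from .data_model import (
    CommunityTable,
    EnvTable,
    bray_curtis,
    diversity,
    euclidean_distance,
    hellinger_transform,
    mao_tau,
)
from .neutral_model import SAD, fit_neutral, neutral_gof
from .ordination_stats import envfit, indval, mantel, nmds
from .phylo_structure import cophenetic_from_newick, nti, patch_nti_test, sample_seed
from .spatial_partition import forward_select, pcnm, varpart

logger = logging.getLogger("amfassembly")

__all__ = ["AnalysisConfig", "run_full_analysis"]


@dataclass
class AnalysisConfig:
    """Knobs of the full analysis; defaults follow the published protocol."""

    seed: int = 42
    n_perm: int = 999  # permutations for envfit / Mantel / IndVal / selection
    n_sims: int = 200  # simulated abundance distributions for the neutral GOF
    n_null: int = 999  # taxon-label randomizations for the NTI null
    indval_threshold: float = 0.6
    alpha: float = 0.05
    nmds_k: int = 2
    nmds_restarts: int = 20
    holm: bool = False  # optional multiplicity correction for envfit/IndVal


def _holm(pvals: pd.Series) -> pd.Series:
    order = pvals.sort_values().index
    m = len(order)
    adj, running = {}, 0.0
    for rank, name in enumerate(order):
        running = max(running, min(1.0, (m - rank) * pvals[name]))
        adj[name] = running
    return pd.Series(adj).reindex(pvals.index)


def _config_hash(cfg: AnalysisConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True).encode()
    ).hexdigest()[:16]


def run_full_analysis(
    community: CommunityTable,
    env: EnvTable | None = None,
    coords: pd.DataFrame | None = None,
    tree: str | None = None,
    config: AnalysisConfig | None = None,
) -> dict:
    """Run every analysis stage the inputs support; return a nested report."""
    cfg = config or AnalysisConfig()
    report: dict = {
        "provenance": {
            "version": __version__,
            "config": asdict(cfg),
            "config_hash": _config_hash(cfg),
        },
        "stages": {},
        "errors": {},
    }
    md = community.metadata
    groups = md["patch"] if md is not None and "patch" in md else None
    root_systems = (
        sorted(md["root_system"].unique())
        if md is not None and "root_system" in md
        else [None]
    )

    def by_root(rs):
        if rs is None:
            return community
        ids = md.index[md["root_system"] == rs]
        return community.subset_samples(ids)

    # --- diversity and rarefaction ---------------------------------------
    try:
        div = diversity(community)
        rare = {}
        for rs in root_systems:
            sub = by_root(rs)
            curve = mao_tau(sub)
            rare[str(rs)] = {"h": curve.h.tolist(), "tau": curve.tau.tolist()}
        report["stages"]["diversity"] = {
            "per_sample": div.to_dict(orient="index"),
            "rarefaction": rare,
            "n_phylotypes": int((community.values().sum(axis=0) > 0).sum()),
            "richness_by_root_system": {
                str(rs): int((by_root(rs).values().sum(axis=0) > 0).sum())
                for rs in root_systems
            },
        }
    except Exception as exc:  # noqa: BLE001 - partial reports by design
        report["errors"]["diversity"] = f"{type(exc).__name__}: {exc}"

    # --- ordination statistics -------------------------------------------
    for rs in root_systems:
        key = f"ordination[{rs}]"
        try:
            sub = by_root(rs)
            if len(sub.sample_ids) < cfg.nmds_k + 2:
                logger.info("skipping %s: too few samples", key)
                continue
            dm = bray_curtis(sub)
            ordn = nmds(
                dm, k=cfg.nmds_k, restarts=cfg.nmds_restarts, seed=cfg.seed
            )
            entry = {
                "stress": ordn.stress,
                "scores": {
                    sid: ordn.scores[i].tolist()
                    for i, sid in enumerate(ordn.sample_ids)
                },
            }
            if env is not None:
                sub_env = env.aligned_to(sub.sample_ids)
                ef = envfit(ordn, sub_env, n_perm=cfg.n_perm, seed=cfg.seed)
                tab = ef.table.copy()
                if cfg.holm:
                    tab["P_holm"] = _holm(tab["P"])
                entry["envfit"] = tab.to_dict(orient="index")
                d_env = euclidean_distance(
                    (sub_env.table - sub_env.table.mean()) / sub_env.table.std(ddof=0)
                )
                d_env.ids = sub.sample_ids
                mres = mantel(dm, d_env, n_perm=cfg.n_perm, seed=cfg.seed)
                entry["mantel_env"] = {"r": mres.r, "P": mres.P}
            if groups is not None and groups.loc[sub.sample_ids].nunique() >= 2:
                iv = indval(
                    sub, groups.loc[sub.sample_ids], n_perm=cfg.n_perm,
                    seed=cfg.seed, threshold=cfg.indval_threshold,
                )
                tab = iv.table.copy()
                if cfg.holm:
                    tab["P_holm"] = _holm(tab["P"])
                entry["indval"] = tab.to_dict(orient="index")
            report["stages"][key] = entry
        except Exception as exc:  # noqa: BLE001
            report["errors"][key] = f"{type(exc).__name__}: {exc}"

    # --- neutral model per root system ------------------------------------
    for rs in root_systems:
        key = f"neutral[{rs}]"
        try:
            pooled = by_root(rs).pooled()
            sad = SAD.from_counts(np.rint(pooled.to_numpy()))
            fit = fit_neutral(sad)
            gof = neutral_gof(sad, fit, n_sims=cfg.n_sims, seed=cfg.seed)
            report["stages"][key] = {
                "J": sad.J, "S": sad.S,
                "theta": fit.theta, "I": fit.I, "m": fit.m,
                "logL": fit.logL, "converged": fit.converged,
                "chi2": gof.chi2, "df": gof.df, "chi2_P": gof.chi2_P,
                "ks_D": gof.ks_D, "ks_Z": gof.ks_Z, "ks_P": gof.ks_P,
            }
        except Exception as exc:  # noqa: BLE001
            report["errors"][key] = f"{type(exc).__name__}: {exc}"

    # --- phylogenetic structure -------------------------------------------
    if tree is None:
        logger.info("no tree supplied: phylogenetic stage skipped")
    else:
        try:
            pdist_phylo = cophenetic_from_newick(tree)
            taxa = community.phylotype_ids
            per_sample = {}
            for sid in community.sample_ids:
                a = community.abundance.loc[sid].to_numpy(dtype=float)
                if (a > 0).sum() < 2:
                    continue
                res = nti(
                    a, taxa, pdist_phylo, n_null=cfg.n_null,
                    seed=sample_seed(cfg.seed, sid),
                )
                per_sample[sid] = {
                    "mntd_obs": res.mntd_obs, "null_mean": res.null_mean,
                    "null_sd": res.null_sd, "nti": res.nti,
                    "degenerate": res.degenerate,
                }
            summary = {}
            if md is not None and {"patch", "root_system"} <= set(md.columns):
                for (patch, rs), ids in md.groupby(["patch", "root_system"]).groups.items():
                    vals = [
                        per_sample[s]["nti"] for s in ids if s in per_sample
                    ]
                    if len(vals) >= 2:
                        mean, se, tstat, p = patch_nti_test(vals)
                        summary[f"{patch}|{rs}"] = {
                            "mean": mean, "se": se, "t": tstat, "P": p,
                            "n": len(vals),
                        }
            report["stages"]["phylo"] = {
                "per_sample": per_sample, "patch_tests": summary,
            }
        except Exception as exc:  # noqa: BLE001
            report["errors"]["phylo"] = f"{type(exc).__name__}: {exc}"

    # --- spatial variation partitioning ------------------------------------
    if coords is None or env is None:
        logger.info("coordinates or environment missing: spatial stage skipped")
    else:
        for rs in root_systems:
            key = f"varpart[{rs}]"
            try:
                sub = by_root(rs)
                xy = coords.loc[sub.sample_ids].to_numpy(dtype=float)
                basis = pcnm(xy)
                y = hellinger_transform(sub).values()
                y = y - y.mean(axis=0)
                sel = forward_select(
                    y, basis.vectors, n_perm=cfg.n_perm, alpha=cfg.alpha,
                    seed=cfg.seed,
                )
                env_mat = env.aligned_to(sub.sample_ids).table.to_numpy(dtype=float)
                if not sel:
                    logger.info("%s: no spatial eigenfunctions selected", key)
                spa = basis.vectors[:, sel] if sel else basis.vectors[:, :1] * 0.0
                vp = varpart(y, env_mat, spa)
                report["stages"][key] = {
                    "n_pcnm": int(basis.vectors.shape[1]),
                    "selected_pcnm": sel,
                    **vp.as_dict(),
                }
            except Exception as exc:  # noqa: BLE001
                report["errors"][key] = f"{type(exc).__name__}: {exc}"

    return report
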