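"""Community data structures, file I/O, transforms, distances, diversity and rarefaction.

The central container is :class:`CommunityTable`, a samples x phylotypes
abundance matrix with per-sample metadata (patch, root system, coordinates).
Abundances are clone counts when integer-valued, otherwise relative
abundances (percentages in the packaged field table).

The packaged fixture is the published relative-abundance table of 30
arbuscular mycorrhizal (AM) fungal phylotypes detected in roots of the toxic
forb *Ligularia virgaurea* and of its neighborhood plants across four meadow
patches spanning a density gradient of the forb (Control, LD, MD, HD).
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln

__all__ = [
    "CommunityTable",
    "DistanceMatrix",
    "RarefactionCurve",
    "EnvTable",
    "STUDY_CONSTANTS",
    "read_community_table",
    "read_env_table",
    "table1_fixture",
    "table1_totals",
    "am_sequence_fraction",
    "reconstruct_counts",
    "hellinger_transform",
    "bray_curtis",
    "euclidean_distance",
    "diversity",
    "mao_tau",
]

#: Bookkeeping constants of the field study the fixture comes from: clone
#: libraries were screened by RFLP and 435 representative clones sequenced,
#: of which 324 proved AM-fungal; the 30 phylotypes rest on 1184 AM clones
#: from 35 root samples (15 focal, 20 neighborhood).
STUDY_CONSTANTS = {
    "n_sequences_total": 435,
    "n_sequences_am": 324,
    "n_am_clones": 1184,
    "n_samples": 35,
    "n_samples_focal": 15,
    "n_samples_neighborhood": 20,
}


def am_sequence_fraction() -> float:
    """Percentage of sequenced clones identified as AM-fungal, to one decimal."""
    c = STUDY_CONSTANTS
    return round(100.0 * c["n_sequences_am"] / c["n_sequences_total"], 1)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class CommunityTable:
    """Samples x phylotypes abundance matrix plus per-sample metadata.

    Parameters
    ----------
    abundance
        DataFrame indexed by sample id, one column per phylotype,
        non-negative values.
    metadata
        Optional DataFrame aligned to the same sample ids, with columns such
        as ``patch``, ``root_system``, ``x``, ``y``.
    """

    abundance: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        ab = self.abundance
        if ab.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if ab.columns.duplicated().any():
            raise ValueError("duplicate phylotype ids")
        vals = ab.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("non-finite abundance values")
        if (vals < 0).any():
            raise ValueError("negative abundance values")
        if self.metadata is not None:
            md = self.metadata
            if list(md.index) != list(ab.index):
                md = md.reindex(ab.index)
                if md.isna().all(axis=1).any():
                    raise ValueError("metadata rows do not align with abundance rows")
                self.metadata = md

    # convenience -----------------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.abundance.index)

    @property
    def phylotype_ids(self) -> list:
        return list(self.abundance.columns)

    def values(self) -> np.ndarray:
        return self.abundance.to_numpy(dtype=float)

    def __getitem__(self, key):
        """``table["Glo-2", "Nb-HD"]`` -> abundance of that phylotype/sample."""
        phylotype, sample = key
        return float(self.abundance.loc[sample, phylotype])

    def subset_samples(self, sample_ids: Sequence) -> "CommunityTable":
        md = self.metadata.loc[list(sample_ids)] if self.metadata is not None else None
        return CommunityTable(self.abundance.loc[list(sample_ids)].copy(), md)

    def pooled(self, sample_ids: Sequence | None = None) -> pd.Series:
        """Sum abundances over samples (all by default), one value per phylotype."""
        ab = self.abundance if sample_ids is None else self.abundance.loc[list(sample_ids)]
        return ab.sum(axis=0)

    def relative_abundance(self) -> "CommunityTable":
        rs = self.abundance.sum(axis=1)
        if (rs <= 0).any():
            raise ValueError("all-zero sample row")
        return CommunityTable(self.abundance.div(rs, axis=0), self.metadata)


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with zero diagonal, keyed by ids."""

    ids: list
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")
        if (d < -1e-12).any():
            raise ValueError("negative distances")
        self.d = d

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


@dataclass
class RarefactionCurve:
    """Sample-based rarefaction: expected richness tau(h) for h = 1..H."""

    h: np.ndarray
    tau: np.ndarray
    incidence: pd.Series  # per-phylotype number of occupied samples


@dataclass
class EnvTable:
    """Named numeric environment variables (soil/plant measurements) per sample."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("duplicate sample ids in environment table")
        vals = self.table.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("non-finite environment values")

    @property
    def sample_ids(self) -> list:
        return list(self.table.index)

    @property
    def variables(self) -> list:
        return list(self.table.columns)

    def aligned_to(self, sample_ids: Sequence) -> "EnvTable":
        missing = set(sample_ids) - set(self.table.index)
        if missing:
            raise ValueError(f"environment table missing samples: {sorted(missing)}")
        return EnvTable(self.table.loc[list(sample_ids)].copy())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_community_table(path, metadata_path=None) -> CommunityTable:
    """Read a TSV community table (samples as rows, header = phylotype ids).

    An optional metadata sidecar TSV carries ``sample_id``, ``patch``,
    ``root_system`` and optional ``x``/``y`` coordinate columns.
    """
    ab = pd.read_csv(path, sep="\t", index_col=0)
    try:
        ab = ab.astype(float)
    except ValueError as exc:
        raise ValueError(f"malformed community table {path}: {exc}") from exc
    md = None
    if metadata_path is not None:
        md = pd.read_csv(metadata_path, sep="\t", index_col=0)
    return CommunityTable(ab, md)


def read_env_table(path) -> EnvTable:
    return EnvTable(pd.read_csv(path, sep="\t", index_col=0).astype(float))


def table1_fixture() -> CommunityTable:
    """The packaged published relative-abundance table.

    Thirty AM fungal phylotypes (rows of the printed table, columns here) by
    seven pooled communities: LD/MD/HD patches of *L. virgaurea* roots and
    Control/LD/MD/HD patches of neighborhood-plant roots.  Values are
    percentages of clone numbers, exactly as printed.
    """
    data_dir = importlib.resources.files("amfassembly") / "data"
    with importlib.resources.as_file(data_dir / "table1_relabund.tsv") as p_ab, \
            importlib.resources.as_file(data_dir / "table1_metadata.tsv") as p_md:
        return read_community_table(p_ab, p_md)


def table1_totals() -> dict[str, int]:
    """Per-column clone totals assumed when de-percentaging the fixture.

    The study reports 1184 AM clones over 35 samples (15 focal + 20
    neighborhood) but no per-patch totals, so totals are apportioned by
    sample count and split equally across patches within a root system:
    J = round(1184*15/35) = 507 for the focal plant (169 per patch) and
    J = round(1184*20/35) = 677 for neighborhood plants (170+169*3).
    """
    return {
        "Lv-LD": 169, "Lv-MD": 169, "Lv-HD": 169,
        "Nb-Control": 170, "Nb-LD": 169, "Nb-MD": 169, "Nb-HD": 169,
    }


def reconstruct_counts(
    rel: CommunityTable, totals: Mapping[str, int]
) -> tuple[CommunityTable, dict[str, int]]:
    """Invert a percentage table into integer clone counts.

    Each cell becomes ``round(pct * total / 100)`` (round-half-even).  Because
    printed percentages are themselves rounded, the per-sample sum of counts
    can miss the requested total by a few clones; the discrepancy
    ``sum(counts) - total`` is returned per sample rather than silently
    redistributed.
    """
    ab = rel.abundance
    counts = {}
    discrepancy = {}
    for sid in ab.index:
        total = int(totals[sid])
        if total <= 0:
            raise ValueError(f"non-positive total for sample {sid}")
        row = np.rint(ab.loc[sid].to_numpy(dtype=float) * total / 100.0).astype(int)
        counts[sid] = row
        discrepancy[sid] = int(row.sum()) - total
    out = pd.DataFrame.from_dict(counts, orient="index", columns=ab.columns).loc[ab.index]
    return CommunityTable(out.astype(float), rel.metadata), discrepancy


# ---------------------------------------------------------------------------
# Transforms and distances
# ---------------------------------------------------------------------------

def hellinger_transform(t: CommunityTable) -> CommunityTable:
    """Square root of row-normalized abundances.

    Gives rare and dominant phylotypes commensurate weight and makes
    Euclidean-geometry methods (RDA, PCA) appropriate for count data: each
    output row has squared entries summing to one.
    """
    vals = t.values()
    rs = vals.sum(axis=1)
    if (rs <= 0).any():
        bad = [t.sample_ids[i] for i in np.where(rs <= 0)[0]]
        raise ValueError(f"all-zero sample rows: {bad}")
    out = np.sqrt(vals / rs[:, None])
    return CommunityTable(
        pd.DataFrame(out, index=t.abundance.index, columns=t.abundance.columns),
        t.metadata,
    )


def bray_curtis(t: CommunityTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) between sample rows."""
    vals = t.values()
    if vals.shape[0] < 2:
        raise ValueError("need at least two samples")
    rs = vals.sum(axis=1)
    if (rs <= 0).any():
        raise ValueError("Bray-Curtis undefined for all-zero sample rows")
    return DistanceMatrix(t.sample_ids, squareform(pdist(vals, metric="braycurtis")))


def euclidean_distance(m, ids: Sequence | None = None) -> DistanceMatrix:
    """Euclidean distance between rows of a numeric matrix or DataFrame."""
    if isinstance(m, EnvTable):
        m = m.table
    if isinstance(m, pd.DataFrame):
        if ids is None:
            ids = list(m.index)
        m = m.to_numpy(dtype=float)
    m = np.asarray(m, dtype=float)
    if ids is None:
        ids = list(range(m.shape[0]))
    return DistanceMatrix(list(ids), squareform(pdist(m, metric="euclidean")))


# ---------------------------------------------------------------------------
# Diversity and rarefaction
# ---------------------------------------------------------------------------

def diversity(t: CommunityTable, base: float | None = None) -> pd.DataFrame:
    """Per-sample phylotype richness and Shannon diversity.

    Richness counts phylotypes with abundance strictly greater than zero.
    Shannon H = -sum p log p over relative abundances; natural log by
    default, ``base`` to change it.
    """
    vals = t.values()
    rs = vals.sum(axis=1)
    if (rs <= 0).any():
        raise ValueError("all-zero sample row")
    p = vals / rs[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h = -plogp.sum(axis=1)
    if base is not None:
        h = h / math.log(base)
    return pd.DataFrame(
        {"richness": (vals > 0).sum(axis=1), "shannon": h},
        index=t.abundance.index,
    )


def mao_tau(t: CommunityTable) -> RarefactionCurve:
    """Analytical sample-based rarefaction (Mao Tau).

    With H samples and incidence H_j (samples occupied by phylotype j), the
    expected richness in a random h-sample subset is

        tau(h) = S_obs - sum_j C(H - H_j, h) / C(H, h),

    the mean over all C(H, h) subsets; tau(H) equals observed richness.
    """
    vals = t.values()
    H = vals.shape[0]
    if H < 1:
        raise ValueError("need at least one sample")
    inc = (vals > 0).sum(axis=0)
    present = inc > 0
    s_obs = int(present.sum())
    hj = inc[present].astype(int)
    hs = np.arange(1, H + 1)
    tau = np.empty(H, dtype=float)
    for i, h in enumerate(hs):
        # log C(H - Hj, h) - log C(H, h); zero when H - Hj < h
        ok = (H - hj) >= h
        miss = np.zeros(len(hj))
        if ok.any():
            a = H - hj[ok]
            log_ratio = (
                gammaln(a + 1) - gammaln(h + 1) - gammaln(a - h + 1)
                - (gammaln(H + 1) - gammaln(h + 1) - gammaln(H - h + 1))
            )
            miss[ok] = np.exp(log_ratio)
        tau[i] = s_obs - miss.sum()
    return RarefactionCurve(
        h=hs,
        tau=tau,
        incidence=pd.Series(inc, index=t.abundance.columns),
    )
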