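"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from amfassembly import (
    CommunityTable,
    reconstruct_counts,
    table1_fixture,
    table1_totals,
)


# ---------------------------------------------------------------------------
# Oracles (kept independent of the implementation paths they check)
# ---------------------------------------------------------------------------

def partitions(n: int, maxpart: int | None = None):
    """All integer partitions of n (tuples in weakly decreasing order)."""
    if maxpart is None:
        maxpart = n
    if n == 0:
        yield ()
        return
    for k in range(min(n, maxpart), 0, -1):
        for rest in partitions(n - k, k):
            yield (k,) + rest


def exhaustive_rarefaction(presence: np.ndarray, h: int) -> float:
    """Mean richness over all h-sample subsets (brute force)."""
    H = presence.shape[0]
    richness = []
    for combo in itertools.combinations(range(H), h):
        sub = presence[list(combo)]
        richness.append(int((sub.any(axis=0)).sum()))
    return float(np.mean(richness))


def brute_force_mntd(d: np.ndarray, abundance: np.ndarray) -> float:
    """Abundance-weighted MNTD via explicit nearest-neighbour search."""
    present = np.where(abundance > 0)[0]
    w = abundance[present] / abundance[present].sum()
    total = 0.0
    for wi, i in zip(w, present):
        total += wi * min(d[i, j] for j in present if j != i)
    return total


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture(scope="session")
def table1_counts(table1):
    counts, discrepancy = reconstruct_counts(table1, table1_totals())
    return counts, discrepancy


@pytest.fixture(scope="session")
def pooled_sads(table1_counts):
    """Pooled integer SAD vectors per root system from the packaged table."""
    counts, _ = table1_counts
    md = counts.metadata
    out = {}
    for rs in ("focal", "neighborhood"):
        ids = md.index[md["root_system"] == rs]
        out[rs] = counts.pooled(ids).to_numpy()
    return out


@pytest.fixture
def small_community():
    ab = pd.DataFrame(
        [[3.0, 1.0, 0.0], [0.0, 2.0, 2.0], [1.0, 1.0, 1.0], [5.0, 0.0, 1.0]],
        index=["s1", "s2", "s3", "s4"],
        columns=["A", "B", "C"],
    )
    md = pd.DataFrame(
        {"patch": ["P1", "P1", "P2", "P2"],
         "root_system": ["focal"] * 4},
        index=ab.index,
    )
    return CommunityTable(ab, md)


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)
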