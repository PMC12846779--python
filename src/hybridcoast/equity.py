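"""Distributional analysis of restoration benefits.

Population is split into three groups: (i) outside flood-prone areas,
(ii) inside flood-prone areas, and (iii) inside flood-prone areas that also
stand to benefit from mangrove restoration (group iii is a subset of ii).
Flood-prone is operationalised as the undefended 1,000-y inundation extent
(configurable).  The groups are overlaid with a poverty-likelihood grid
(expected counts of people below the poverty line) and with the wealth
index (population-weighted normalized distributions), and wealth
differences between groups are tested with the Mann-Whitney U rank test:
midranks for ties, tie-corrected normal approximation with continuity
correction, and exact enumeration for small samples.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, norm

from .errors import ParameterError

logger = logging.getLogger(__name__)

#: exact enumeration is used when the pooled sample is at most this large
EXACT_LIMIT = 12
#: cap on the population-weighted resampling used for rank tests
RESAMPLE_BUDGET = 20000
FLOOD_PRONE_RP = 1000.0


@dataclass
class PopulationGroups:
    """Cell masks of the three population groups (populated cells only)."""

    outside: np.ndarray
    flood_prone: np.ndarray
    benefit: np.ndarray

    def __post_init__(self):
        if (self.benefit & ~self.flood_prone).any():
            raise ParameterError("benefit group must be inside flood-prone")
        if (self.outside & self.flood_prone).any():
            raise ParameterError("groups 1 and 2 must be disjoint")

    def items(self):
        return (("outside", self.outside), ("flood_prone", self.flood_prone),
                ("benefit", self.benefit))


@dataclass(frozen=True)
class RankTestResult:
    U1: float
    U2: float
    z: float
    p: float
    n1: int
    n2: int
    exact: bool


def group_masks(flood_extent, benefit_transects, catchment: np.ndarray,
                population: np.ndarray) -> PopulationGroups:
    """Build the three group masks.

    ``flood_extent`` is the undefended large-event DepthGrid (or boolean
    mask); ``benefit_transects`` the ids of transects with restorable width
    and positive avoided damages; ``catchment`` the per-cell transect id of
    the flood pathway.
    """
    prone = flood_extent.flooded if hasattr(flood_extent, "flooded") \
        else np.asarray(flood_extent, dtype=bool)
    populated = population > 0
    if not populated.any():
        logger.warning("no populated cells: equity groups are empty")
    benefit_ids = set(int(t) for t in benefit_transects)
    in_benefit = np.isin(catchment, sorted(benefit_ids)) if benefit_ids \
        else np.zeros_like(prone)
    return PopulationGroups(outside=populated & ~prone,
                            flood_prone=populated & prone,
                            benefit=populated & prone & in_benefit)


def poverty_table(population: np.ndarray, poverty_p: np.ndarray,
                  groups: PopulationGroups,
                  growth_to_2050: float = 1.0) -> pd.DataFrame:
    """Expected poor counts and percentages per group, now and in 2050.

    The 2050 row scales population by the scenario growth factor with the
    poverty likelihood held fixed.
    """
    if np.any(poverty_p < 0) or np.any(poverty_p > 1):
        raise ParameterError("poverty_p must lie in [0, 1]")
    rows = []
    for year, factor in (("present", 1.0), (2050, growth_to_2050)):
        for name, mask in groups.items():
            total = float(population[mask].sum()) * factor
            poor = float((population[mask] * poverty_p[mask]).sum()) * factor
            pct = poor / total * 100.0 if total > 0 else math.nan
            rows.append({"group": name, "year": year, "total": total,
                         "poor": poor, "pct_poor": pct})
    return pd.DataFrame(rows)


def wealth_distribution(wealth: np.ndarray, population: np.ndarray,
                        mask: np.ndarray, bins) -> tuple:
    """Population-weighted wealth histogram normalized to unit area.

    Returns (bin_edges, density); empty mask -> zero density.
    """
    edges = np.asarray(bins, dtype=float)
    w = wealth[mask]
    pop = population[mask]
    if w.size == 0 or pop.sum() == 0:
        return edges, np.zeros(edges.size - 1)
    counts, edges = np.histogram(w, bins=edges, weights=pop)
    widths = np.diff(edges)
    density = counts / (counts * widths).sum()
    return edges, density


def weighted_sample(wealth: np.ndarray, population: np.ndarray,
                    mask: np.ndarray, rng: np.random.Generator,
                    budget: int = RESAMPLE_BUDGET) -> np.ndarray:
    """Wealth values repeated by rounded population counts, subsampled to
    the resampling budget."""
    w = wealth[mask]
    counts = np.round(population[mask]).astype(int)
    sel = counts > 0
    values = np.repeat(w[sel], counts[sel])
    if values.size > budget:
        values = rng.choice(values, size=budget, replace=False)
    return values


def _u_statistic(a: np.ndarray, b: np.ndarray) -> tuple:
    """Midrank-based U1, U2 and the tie vector of the pooled sample."""
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    R1 = ranks[:n1].sum()
    U1 = R1 - n1 * (n1 + 1) / 2.0
    U2 = n1 * n2 - U1
    _, tie_counts = np.unique(pooled, return_counts=True)
    return U1, U2, tie_counts


def _exact_p(a: np.ndarray, b: np.ndarray, u1: float) -> float:
    """Two-sided permutation p: share of labelings at least as extreme
    (in |U - n1 n2 / 2|) as the observed split."""
    n1 = len(a)
    pooled = np.concatenate([a, b])
    n = len(pooled)
    ranks = rankdata(pooled)
    mu = n1 * (n - n1) / 2.0
    obs = abs(u1 - mu)
    hits = total = 0
    offset = n1 * (n1 + 1) / 2.0
    for idx in itertools.combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        total += 1
        if abs(u - mu) >= obs - 1e-12:
            hits += 1
    return hits / total


def mann_whitney(sample_a, sample_b) -> RankTestResult:
    """Two-sided Mann-Whitney U test.

    Uses exact enumeration of all labelings when n1 + n2 <= 12; otherwise a
    tie-corrected normal approximation with 0.5 continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 1 or n2 < 1:
        raise ParameterError("both samples must be nonempty")
    U1, U2, ties = _u_statistic(a, b)
    N = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = float(((ties ** 3 - ties).sum()) / (N * (N - 1))) if N > 1 else 0.0
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var <= 0:  # all pooled values identical
        return RankTestResult(U1=U1, U2=U2, z=0.0, p=1.0, n1=n1, n2=n2,
                              exact=False)
    if N <= EXACT_LIMIT:
        p = _exact_p(a, b, U1)
        z = (U1 - mu) / math.sqrt(var)
        return RankTestResult(U1=U1, U2=U2, z=z, p=p, n1=n1, n2=n2, exact=True)
    diff = U1 - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / math.sqrt(var)
    p = min(2.0 * norm.sf(abs(z)), 1.0)
    return RankTestResult(U1=U1, U2=U2, z=z, p=p, n1=n1, n2=n2, exact=False)
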