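"""Community-matrix normalisation and presence-based beta diversity.

A community matrix is a :class:`pandas.DataFrame` of non-negative integer
counts with features (AAVs or OTUs) as rows and samples as columns.  The
functions here implement the normalisation steps applied to such tables
before any modelling — removal of features seen in a single sample and
rarefaction to a common depth — plus richness and pairwise Sørensen
dissimilarity partitioned into its turnover (Simpson) and nestedness
components.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BetaPartition",
    "drop_single_sample_features",
    "rarefy",
    "richness",
    "sorensen_partition",
    "pairwise_dissimilarity",
]


@dataclass(frozen=True)
class BetaPartition:
    """Sørensen dissimilarity between two communities, partitioned.

    Attributes
    ----------
    a : int
        Number of features shared by both communities.
    b, c : int
        Features unique to the first and second community respectively.
    beta_sor : float
        Sørensen dissimilarity ``(b + c) / (2a + b + c)``.
    beta_sim : float
        Simpson dissimilarity (turnover) ``min(b, c) / (a + min(b, c))``.
    beta_sne : float
        Nestedness-resultant component ``beta_sor - beta_sim``.
    undefined : bool
        True when both communities are empty (all ratios undefined; the
        beta_* fields are NaN in that case).
    """

    a: int
    b: int
    c: int
    beta_sor: float
    beta_sim: float
    beta_sne: float
    undefined: bool = False


def drop_single_sample_features(m: pd.DataFrame) -> pd.DataFrame:
    """Remove features that occur (count > 0) in exactly one sample.

    Features absent everywhere are removed too: they carry no information
    and would otherwise survive the occupancy rule.
    """
    occupancy = (m > 0).sum(axis=1)
    kept = m.loc[occupancy >= 2]
    if kept.shape[0] == 0 and m.shape[0] > 0:
        logger.warning(
            "all %d features occurred in fewer than two samples; "
            "matrix is now empty",
            m.shape[0],
        )
    return kept


def rarefy(m: pd.DataFrame, depth: int, seed: int) -> pd.DataFrame:
    """Subsample every column without replacement down to exactly ``depth``.

    Each column is treated as an urn of ``column sum`` individuals and a
    multivariate-hypergeometric draw of ``depth`` of them is taken, so the
    expected rarefied count of a feature is ``depth * count / column_sum``.
    A single draw is made per table; ``seed`` makes it reproducible.

    Raises
    ------
    ValueError
        If ``depth`` exceeds the total count of any sample (the offending
        sample is named).
    """
    if depth < 0:
        raise ValueError("rarefaction depth must be non-negative")
    totals = m.sum(axis=0)
    short = totals[totals < depth]
    if len(short) > 0:
        raise ValueError(
            f"rarefaction depth {depth} exceeds the total count of "
            f"sample(s): {', '.join(map(str, short.index))}"
        )
    rng = np.random.default_rng(seed)
    out = {}
    for sample in m.columns:
        col = m[sample].to_numpy(dtype=np.int64)
        out[sample] = rng.multivariate_hypergeometric(col, depth)
    result = pd.DataFrame(out, index=m.index, columns=m.columns)
    result.attrs["rarefaction_depth"] = depth
    result.attrs["rarefaction_seed"] = seed
    return result


def richness(m: pd.DataFrame) -> pd.Series:
    """Per-sample feature richness: the number of features with count > 0."""
    return (m > 0).sum(axis=0)


def sorensen_partition(x, y) -> BetaPartition:
    """Partition the Sørensen dissimilarity between two presence vectors.

    ``x`` and ``y`` are boolean/0-1 vectors over the same feature universe.
    The dissimilarity (b+c)/(2a+b+c) is split into spatial turnover
    (Simpson dissimilarity) and a nestedness-resultant remainder; the two
    components sum exactly to the total.
    """
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError(
            f"presence vectors have mismatched feature universes: "
            f"{x.shape} vs {y.shape}"
        )
    a = int(np.sum(x & y))
    b = int(np.sum(x & ~y))
    c = int(np.sum(~x & y))
    if a + b + c == 0:
        return BetaPartition(0, 0, 0, float("nan"), float("nan"),
                             float("nan"), undefined=True)
    beta_sor = (b + c) / (2 * a + b + c)
    m_bc = min(b, c)
    # a + min(b,c) == 0 implies a == 0 and one side empty: pure nestedness
    beta_sim = m_bc / (a + m_bc) if (a + m_bc) > 0 else 0.0
    return BetaPartition(a, b, c, beta_sor, beta_sim, beta_sor - beta_sim)


def pairwise_dissimilarity(m: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Sørensen partition for the samples of a community matrix.

    Returns a long-format table with one row per unordered sample pair
    (n*(n-1)/2 rows) and columns ``sample_i, sample_j, a, b, c, beta_sor,
    beta_sim, beta_sne, undefined``.
    """
    if m.shape[1] < 2:
        raise ValueError("need at least two samples for pairwise dissimilarity")
    presence = (m.to_numpy() > 0)
    samples = list(m.columns)
    # shared / unique feature counts via presence cross-products
    p = presence.astype(np.int64)
    shared = p.T @ p
    occ = p.sum(axis=0)
    rows = []
    for i, j in itertools.combinations(range(len(samples)), 2):
        a = int(shared[i, j])
        b = int(occ[i] - a)
        c = int(occ[j] - a)
        if a + b + c == 0:
            rows.append((samples[i], samples[j], 0, 0, 0,
                         np.nan, np.nan, np.nan, True))
            continue
        beta_sor = (b + c) / (2 * a + b + c)
        m_bc = min(b, c)
        beta_sim = m_bc / (a + m_bc) if (a + m_bc) > 0 else 0.0
        rows.append((samples[i], samples[j], a, b, c,
                     beta_sor, beta_sim, beta_sor - beta_sim, False))
    return pd.DataFrame(
        rows,
        columns=["sample_i", "sample_j", "a", "b", "c",
                 "beta_sor", "beta_sim", "beta_sne", "undefined"],
    )
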