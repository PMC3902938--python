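"""Gene-set co-association and term enrichment.

Overlap between two gene sets A and B inside a finite universe of size N is
scored with the hypergeometric distribution: with K = |A|, n = |B| and
k = |A ∩ B|, over-representation is the upper tail P(X >= k) and
under-representation the lower tail P(X <= k).  P-values across a family
of tests are adjusted with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

Q_FLOOR = 1e-300  # floor before -log10 transforms


def hypergeometric_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n) (over-representation)."""
    _check_hyper_args(k, K, n, N)
    # survival function is exclusive, so shift by one
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def hypergeometric_lower(k: int, K: int, n: int, N: int) -> float:
    """P(X <= k) (under-representation tail)."""
    _check_hyper_args(k, K, n, N)
    p = float(hypergeom.cdf(k, N, K, n))
    return min(max(p, 0.0), 1.0)


def _check_hyper_args(k: int, K: int, n: int, N: int) -> None:
    if N < 0 or K > N or n > N:
        raise ValueError(f"invalid universe: K={K}, n={n}, N={N}")
    if k < 0 or k > min(K, n):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")


def bh_adjust(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class EnrichmentResult:
    """Overlap statistics for one pair of gene sets."""

    set_a: str
    set_b: str
    N: int
    K: int
    n: int
    k: int
    p: float
    q: float
    direction: str  # over | under

    def to_dict(self) -> dict:
        return asdict(self)


def _overlap_stats(
    a: frozenset[str], b: frozenset[str], universe: frozenset[str]
) -> tuple[int, int, int, int]:
    a = a & universe
    b = b & universe
    return len(universe), len(a), len(b), len(a & b)


def coassociation_matrix(
    sets_a: GeneSetCollection,
    sets_b: GeneSetCollection,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """All-pairs hypergeometric co-association between two collections.

    Each (A, B) cell reports the upper tail when the overlap exceeds its
    expectation ``K*n/N`` (direction ``over``) and the lower tail otherwise
    (direction ``under``).  BH adjustment is applied across all cells of
    the matrix.  Returns a tidy DataFrame with one row per pair.
    """
    if universe is None:
        uni = sets_a.effective_universe() | sets_b.effective_universe()
    else:
        uni = frozenset(universe)
    if not uni:
        raise ValueError("empty universe")
    rows = []
    for name_a in sets_a:
        for name_b in sets_b:
            N, K, n, k = _overlap_stats(sets_a[name_a], sets_b[name_b], uni)
            expected = K * n / N
            if k >= expected:
                p = hypergeometric_upper(k, K, n, N)
                direction = "over"
            else:
                p = hypergeometric_lower(k, K, n, N)
                direction = "under"
            rows.append(
                EnrichmentResult(name_a, name_b, N, K, n, k, p, np.nan, direction)
            )
    df = pd.DataFrame([r.to_dict() for r in rows])
    df["q"] = bh_adjust(df["p"])
    return df


def term_enrichment(
    query: Iterable[str],
    annotations: GeneSetCollection,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Over-representation of annotation terms in a query gene set.

    BH adjustment is applied across the terms; the result is sorted by q
    then p.  Query genes outside the universe are dropped with a warning.
    """
    import logging

    if universe is None:
        uni = annotations.effective_universe()
    else:
        uni = frozenset(universe)
    query = frozenset(query)
    stray = query - uni
    if stray:
        logging.getLogger(__name__).warning(
            "term enrichment: dropping %d query gene(s) outside the universe",
            len(stray),
        )
        query &= uni
    rows = []
    for term in annotations:
        N, K, n, k = _overlap_stats(annotations[term], query, uni)
        p = hypergeometric_upper(k, K, n, N)
        rows.append(EnrichmentResult(term, "query", N, K, n, k, p, np.nan, "over"))
    df = pd.DataFrame([r.to_dict() for r in rows])
    if len(df):
        df["q"] = bh_adjust(df["p"])
        df = df.sort_values(["q", "p", "set_a"], ignore_index=True)
    return df


def enrichment_heatmap_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy co-association table to a -log10(q) matrix
    (signed: under-representation is shown negative)."""
    sign = np.where(df["direction"] == "over", 1.0, -1.0)
    score = sign * -np.log10(np.maximum(df["q"].to_numpy(), Q_FLOOR))
    tidy = df.assign(score=score)
    return tidy.pivot(index="set_a", columns="set_b", values="score")


def cluster_matrix(matrix: pd.DataFrame) -> dict:
    """Average-linkage (UPGMA) clustering of rows and columns.

    Distances are Euclidean on the (finite) matrix values; returns leaf
    orderings and the scipy linkage arrays for dendrogram rendering.
    Fewer than 2 rows (or columns) yields the identity ordering.
    """
    values = np.nan_to_num(matrix.to_numpy(dtype=float))
    out: dict = {}
    for axis, name in ((0, "row"), (1, "col")):
        data = values if axis == 0 else values.T
        labels = matrix.index if axis == 0 else matrix.columns
        if data.shape[0] < 2:
            out[f"{name}_order"] = list(labels)
            out[f"{name}_linkage"] = None
            continue
        link = average(pdist(data, metric="euclidean"))
        order = leaves_list(link)
        out[f"{name}_order"] = [labels[i] for i in order]
        out[f"{name}_linkage"] = link
    return out


def overlap_counts(sets: GeneSetCollection) -> dict[str, int]:
    """Counts of every non-empty membership pattern across <= 6 sets.

    Pattern keys are bit strings in the order of the collection's set
    names ('10' = in first set only).  Counts sum to the union size.
    """
    names = list(sets)
    if len(names) > 6:
        raise ValueError("overlap_counts supports at most 6 sets")
    union: set[str] = set()
    for name in names:
        union |= sets[name]
    counts: dict[str, int] = {}
    for gene in union:
        key = "".join("1" if gene in sets[name] else "0" for name in names)
        counts[key] = counts.get(key, 0) + 1
    # include all-zero-free full pattern space for the declared sets
    for i in range(1, 2 ** len(names)):
        key = format(i, f"0{len(names)}b")
        counts.setdefault(key, 0)
    return counts
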