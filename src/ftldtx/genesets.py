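"""Gene-set arithmetic and inference.

Venn partitions of subtype-correlated gene lists, the uniqueness index and
its |r|-threshold sweep, one-tailed Fisher (hypergeometric) overlap tests,
2×2 chi-squared proportion comparisons, resampling overlap nulls,
nearest-neighbour gene-length matching, and a generic over-representation
core with Holm adjustment.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, hypergeom
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# Venn partitions and the uniqueness index
# ---------------------------------------------------------------------------

def partition_unique_shared(sets: Mapping[str, set]) -> dict[tuple[str, ...], int]:
    """Exact inclusion–exclusion partition of named gene sets.

    Returns counts keyed by the sorted tuple of set names each gene belongs
    to (singleton key = unique to that set).  Counts sum to |union|.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    names = sorted(sets)
    counts: dict[tuple[str, ...], int] = {}
    union = set().union(*sets.values())
    for g in union:
        key = tuple(n for n in names if g in sets[n])
        counts[key] = counts.get(key, 0) + 1
    # make every non-empty membership pattern explicit
    for k in range(1, len(names) + 1):
        for combo in itertools.combinations(names, k):
            counts.setdefault(combo, 0)
    return counts


def uniqueness_index(partition: Mapping[tuple[str, ...], int]) -> float | None:
    """(sum of unique counts) / (sum of all shared counts) over 3 sets.

    Returns None (undefined) when no gene is shared by two or more sets.
    """
    names = sorted({n for key in partition for n in key})
    if len(names) != 3:
        raise ValueError("uniqueness index is defined for exactly 3 sets")
    unique = sum(v for k, v in partition.items() if len(k) == 1)
    shared = sum(v for k, v in partition.items() if len(k) >= 2)
    if shared == 0:
        return None
    return unique / shared


@dataclasses.dataclass
class SweepTable:
    """Uniqueness-index sweep over |r| thresholds."""

    table: pd.DataFrame        # one row per tau: counts and U
    tau_star: float | None     # smallest tau reaching 90% of max defined U


def threshold_sweep(tables: Mapping[str, pd.DataFrame],
                    taus: Sequence[float] = tuple(np.round(np.arange(0, 0.501, 0.05), 2)),
                    alpha: float = 0.05,
                    plateau_fraction: float = 0.9) -> SweepTable:
    """Re-select genes at each |r| threshold and track the uniqueness index.

    `tables` maps subtype name -> GeneCorrelationTable with columns r and
    p_fdr (three subtypes).  tau* is the smallest threshold whose U reaches
    `plateau_fraction` of the maximum defined U; the full table is always
    emitted.  If U is undefined at every threshold, tau_star is None.
    """
    names = sorted(tables)
    if len(names) != 3:
        raise ValueError("threshold sweep expects exactly 3 subtype tables")
    rows = []
    for tau in taus:
        sets = {
            n: set(t.index[(t["p_fdr"] < alpha) & (t["r"].abs() >= tau)])
            for n, t in tables.items()
        }
        part = partition_unique_shared(sets)
        u = uniqueness_index(part)
        row = {"tau": tau, "U": np.nan if u is None else u}
        for key, v in part.items():
            row["+".join(key)] = v
        rows.append(row)
    df = pd.DataFrame(rows).set_index("tau")
    defined = df["U"].dropna()
    if defined.empty:
        return SweepTable(table=df, tau_star=None)
    target = plateau_fraction * defined.max()
    tau_star = float(defined.index[defined >= target][0])
    return SweepTable(table=df, tau_star=tau_star)


# ---------------------------------------------------------------------------
# Overlap tests
# ---------------------------------------------------------------------------

def fisher_overlap(set_a: Iterable, set_b: Iterable,
                   background: Iterable) -> tuple[int, float]:
    """One-tailed Fisher enrichment of the overlap of two gene sets.

    P(X >= observed overlap) under the hypergeometric with margins |A|, |B|
    and universe size N; exact tail summation.
    """
    A, B, U = set(set_a), set(set_b), set(background)
    if not A or not B:
        raise ValueError("empty gene set")
    if not A <= U or not B <= U:
        raise ValueError("sets must be subsets of the background universe")
    k = len(A & B)
    p = float(hypergeom.sf(k - 1, len(U), len(A), len(B)))
    return k, p


def fisher_overlap_counts(k: int, size_a: int, size_b: int, n: int) -> float:
    """Upper-tail Fisher P from counts alone (overlap k of sets of size_a,
    size_b in a universe of n genes)."""
    if not (0 <= k <= min(size_a, size_b) and size_a <= n and size_b <= n):
        raise ValueError("inconsistent counts")
    return float(hypergeom.sf(k - 1, n, size_a, size_b))


def chisq_proportions(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pearson chi-squared comparing two proportions k1/n1 vs k2/n2.

    No continuity correction (matches the printed statistics this package
    reproduces); 1 degree of freedom.
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2) or n1 <= 0 or n2 <= 0:
        raise ValueError("need 0 <= k <= n and n > 0")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate table: zero margin")
    stat, p, _, _ = chi2_contingency(table, correction=False)
    return float(stat), float(p)


def resample_overlap_null(pool: Iterable, size: int, query: Iterable,
                          B: int = 5000, *, seed: int = 0,
                          observed: int | None = None,
                          alternative: str = "greater"
                          ) -> tuple[np.ndarray, float | None]:
    """Null distribution of |sample ∩ query| for random subsets of the pool.

    Draws B uniform without-replacement samples of `size` genes from the
    pool and counts overlap with the query set.  If `observed` is given the
    empirical P in the declared direction is returned alongside.
    """
    pool = list(pool)
    query = set(query)
    if size > len(pool):
        raise ValueError("size exceeds pool")
    rng = np.random.default_rng(seed)
    is_query = np.fromiter((g in query for g in pool), dtype=bool)
    null = np.empty(B, dtype=int)
    for b in range(B):
        idx = rng.choice(len(pool), size=size, replace=False)
        null[b] = int(is_query[idx].sum())
    p = None
    if observed is not None:
        if alternative == "greater":
            p = float(np.mean(null >= observed))
        elif alternative == "less":
            p = float(np.mean(null <= observed))
        else:
            raise ValueError("alternative must be 'greater' or 'less'")
    return null, p


# ---------------------------------------------------------------------------
# Length matching
# ---------------------------------------------------------------------------

def match_by_length(query_lengths: pd.Series,
                    candidate_lengths: pd.Series) -> pd.Series:
    """Greedy 1:1 nearest-neighbour matching on log gene length.

    Queries are processed in descending length; each takes the unused
    candidate minimizing |log L_q − log L_c| (ties by candidate id order).
    Returns query id -> matched candidate id.
    """
    if len(candidate_lengths) < len(query_lengths):
        raise ValueError("insufficient candidates for 1:1 matching")
    if (query_lengths <= 0).any() or (candidate_lengths <= 0).any():
        raise ValueError("lengths must be positive")
    cand = candidate_lengths.sort_index()
    log_c = np.log(cand.to_numpy(dtype=float))
    used = np.zeros(len(cand), dtype=bool)
    match: dict = {}
    for q in query_lengths.sort_values(ascending=False).index:
        diffs = np.abs(log_c - np.log(query_lengths[q]))
        diffs[used] = np.inf
        j = int(diffs.argmin())  # argmin takes the first minimum: id-order ties
        used[j] = True
        match[q] = cand.index[j]
    return pd.Series(match, name="matched")


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------

def ora_collections(query: Iterable, collections: Mapping[str, Iterable],
                    background: Iterable) -> pd.DataFrame:
    """Fisher over-representation of a query against named gene sets.

    Each term is tested with the one-tailed hypergeometric enrichment
    against the declared background; p-values are Holm step-down adjusted
    across terms.  Returns a table indexed by term with columns overlap,
    term_size, p, p_holm.
    """
    query = set(query)
    U = set(background)
    if not query:
        raise ValueError("empty query set")
    rows = []
    for term, genes in collections.items():
        g = set(genes) & U
        k, p = fisher_overlap(query & U, g, U) if g else (0, 1.0)
        rows.append({"term": term, "overlap": k if g else 0,
                     "term_size": len(g), "p": p})
    df = pd.DataFrame(rows).set_index("term")
    _, p_holm, *_ = multipletests(df["p"].to_numpy(), method="holm")
    df["p_holm"] = p_holm
    return df.sort_values("p")
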