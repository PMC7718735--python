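"""Cross-replicate and cross-bait comparison of interactomes.

Given per-bait interactome tables (one row per prey: mean density, positive
call, status), this module computes:

* replicate agreement — shared-hit fraction (intersection over union of the
  two hit sets) and the Pearson correlation of per-prey mean densities over
  prey positive in at least one replicate (non-hit densities zero-filled);
* per-bait fold-enrichment — a prey is enriched for a bait when it is
  positive there and its mean density is at least ``fold`` times the maximum
  over the other baits (a zero elsewhere makes the ratio infinite, hence
  enriched);
* Venn region counts over the hit sets of k baits;
* annotation-term enrichment of a hit set against the library background by
  the upper-tail hypergeometric test with Bonferroni correction over the
  terms that annotate at least one hit;
* row-wise hierarchical clustering (Euclidean distance, complete linkage)
  of prey × bait density matrices for heatmap display.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

__all__ = [
    "hit_set",
    "replicate_agreement",
    "bait_enrichment",
    "venn_counts",
    "term_enrichment",
    "cluster_rows",
]


def hit_set(table: pd.DataFrame) -> set[str]:
    """Prey called positive in an interactome table."""
    return set(table.loc[table["positive"].astype(bool), "prey"])


def _density_map(table: pd.DataFrame) -> dict[str, float]:
    return dict(zip(table["prey"], table["mean_density"].astype(float)))


def replicate_agreement(a: pd.DataFrame, b: pd.DataFrame) -> dict[str, float]:
    """Agreement between two replicate screens of the same bait.

    Returns ``shared`` (|hits(a) ∩ hits(b)|), ``union`` (|hits(a) ∪ hits(b)|),
    ``percent_shared`` (100·shared/union) and ``pearson_r`` over per-prey
    mean densities of prey positive in at least one replicate, zero-filling
    the density where a prey is not a hit.  The prey universes must match.
    """
    ua, ub = set(a["prey"]), set(b["prey"])
    if ua != ub:
        raise ValueError(
            f"prey universes differ ({len(ua ^ ub)} mismatched identifiers)"
        )
    ha, hb = hit_set(a), hit_set(b)
    union = ha | hb
    shared = ha & hb
    pct = 100.0 * len(shared) / len(union) if union else 100.0
    da, db = _density_map(a), _density_map(b)
    prey = sorted(union)
    xa = np.array([da[p] if p in ha else 0.0 for p in prey])
    xb = np.array([db[p] if p in hb else 0.0 for p in prey])
    if len(prey) >= 2 and np.std(xa) > 0 and np.std(xb) > 0:
        r = float(stats.pearsonr(xa, xb).statistic)
    else:
        r = np.nan
    return {
        "shared": len(shared),
        "union": len(union),
        "percent_shared": pct,
        "pearson_r": r,
    }


def bait_enrichment(
    tables: Sequence[pd.DataFrame], fold: float = 2.0
) -> dict[str, set[str]]:
    """Prey showing ``fold``-or-greater enrichment for a specific bait.

    ``tables`` must carry a ``bait`` column each (one bait per table) and a
    shared prey universe.  A prey is enriched for bait b iff it is positive
    for b and its mean density is ≥ fold × the maximum mean density over the
    other baits; if it is zero everywhere else the ratio is infinite and the
    prey counts as enriched.
    """
    if len(tables) < 2:
        raise ValueError("need at least two baits to compare")
    if fold <= 1.0:
        raise ValueError("fold must be > 1")
    universes = [set(t["prey"]) for t in tables]
    if any(u != universes[0] for u in universes[1:]):
        raise ValueError("tables must share one prey universe")
    baits = [str(t["bait"].iloc[0]) for t in tables]
    dens = {b: _density_map(t) for b, t in zip(baits, tables)}
    hits = {b: hit_set(t) for b, t in zip(baits, tables)}
    out: dict[str, set[str]] = {b: set() for b in baits}
    for p in universes[0]:
        for b in baits:
            if p not in hits[b]:
                continue
            others = [dens[o].get(p, 0.0) for o in baits if o != b]
            m = max(others) if others else 0.0
            if m <= 0.0 or dens[b][p] >= fold * m:
                out[b].add(p)
    return out


def venn_counts(hit_sets: Mapping[str, set]) -> dict[frozenset, int]:
    """Counts of every non-empty Venn region over k ≥ 2 named hit sets.

    Keys are frozensets of set names (the region's membership pattern);
    values count elements belonging to exactly those sets.  Region counts
    sum to the size of the union.
    """
    names = list(hit_sets)
    if len(names) < 2:
        raise ValueError("need at least two sets")
    counts: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(set(hit_sets[n]) for n in combo))
            outside = set.union(
                set(), *(set(hit_sets[n]) for n in names if n not in combo)
            )
            counts[frozenset(combo)] = len(inside - outside)
    return counts


def term_enrichment(
    hits: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    background: Iterable[str],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Hypergeometric term enrichment of a hit set against the library.

    For each term with K annotated preys in the background of size N and k
    annotated preys among the n hits, the raw p-value is the upper-tail
    hypergeometric probability P(X ≥ k).  Bonferroni correction multiplies
    by the number of terms annotating at least one hit; terms annotating no
    hit get p_raw 1 and are excluded from that divisor.  The background set
    is the screened prey library, not the genome.

    Returns one row per term: ``term,k,n,K,N,p_raw,p_adj,significant``,
    sorted by adjusted then raw p-value.
    """
    hits = set(hits)
    background = set(background)
    if not hits <= background:
        raise ValueError(
            f"{len(hits - background)} hit prey(s) missing from the background set"
        )
    term_members: dict[str, set[str]] = {}
    for prey, terms in annotations.items():
        if prey not in background:
            raise ValueError(f"annotated prey {prey!r} not in background")
        for t in terms:
            term_members.setdefault(t, set()).add(prey)
    N, n = len(background), len(hits)
    records = []
    tested = sum(1 for m in term_members.values() if m & hits)
    for term, members in sorted(term_members.items()):
        K = len(members)
        k = len(members & hits)
        if k == 0:
            p_raw = 1.0
            p_adj = 1.0
        else:
            p_raw = float(stats.hypergeom.sf(k - 1, N, K, n))
            p_adj = min(1.0, p_raw * tested)
        records.append(
            {
                "term": term,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p_raw": p_raw,
                "p_adj": p_adj,
                "significant": bool(p_adj < alpha),
            }
        )
    out = pd.DataFrame.from_records(
        records, columns=["term", "k", "n", "K", "N", "p_raw", "p_adj", "significant"]
    )
    return out.sort_values(["p_adj", "p_raw", "term"], kind="stable").reset_index(
        drop=True
    )


def cluster_rows(matrix: pd.DataFrame) -> tuple[list, Optional[np.ndarray]]:
    """Row order and merge list for a heatmap of prey × bait densities.

    Agglomerative clustering with Euclidean distance and complete linkage
    (the defaults of the usual heatmap packages).  Returns ``(order,
    merges)``: ``order`` is the dendrogram leaf order as row labels, and
    ``merges`` the SciPy linkage matrix (``None`` for < 2 rows, where the
    identity ordering is returned).  Ties break toward the lower original
    index (stable lexicographic distance ordering).
    """
    values = np.asarray(matrix, dtype=float)
    if np.isnan(values).any():
        raise ValueError("matrix must be complete; zero-fill non-hits first")
    labels = list(matrix.index) if isinstance(matrix, pd.DataFrame) else list(
        range(values.shape[0])
    )
    if values.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if values.shape[0] < 2:
        return labels, None
    merges = linkage(values, method="complete", metric="euclidean")
    order = [labels[i] for i in leaves_list(merges)]
    return order, merges
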