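"""Right-tailed Fisher gene-set enrichment, rank shifts and tier
cross-referencing.

Association between a query gene set and an annotated function is scored
with the hypergeometric upper tail: with ``k`` overlapping genes, a query
of size ``n``, a function of size ``K`` and a universe of size ``N``,

    p = sum_{i=k}^{min(n, K)} C(K, i) C(N-K, n-i) / C(N, n)

(the observed overlap is included in the tail, the standard right-tailed
Fisher exact convention).  Functions are ranked by ascending p; the
universe defaults to all genes measured, which diverges from
knowledge-base-specific universes used by proprietary tools, so absolute
p-values are comparable only within a run.  No multiple-testing
correction is applied by default since ranks, not significance calls,
drive the analysis; Benjamini–Hochberg q-values are available on request.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import GeneSetCollection, InputError, normalize_symbol

__all__ = [
    "fisher_right_tail",
    "rank_functions",
    "rank_shift",
    "cross_reference_tiers",
    "TierCrossReference",
]


def fisher_right_tail(k: int, n: int, K: int, N: int) -> float:
    """Hypergeometric upper-tail probability of >= k overlaps."""
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise InputError(
            f"invalid contingency counts k={k}, n={n}, K={K}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def rank_functions(gene_set, annotations: GeneSetCollection, universe,
                   exclude: tuple[str, ...] = (),
                   fdr: bool = False) -> pd.DataFrame:
    """Rank annotation sets by right-tailed Fisher p against a gene set.

    Only annotations overlapping the gene set appear; annotations named in
    ``exclude`` (e.g. the function the genes were selected by) are dropped
    before ranking.  Ties in p are ordered by descending overlap, then
    name.  Columns: function, k, n, K, N, p (+ q when ``fdr``), rank.
    """
    universe = frozenset(normalize_symbol(g) for g in universe)
    if not universe:
        raise InputError("empty universe")
    query = frozenset(normalize_symbol(g) for g in gene_set) & universe
    rows = []
    for name, members in annotations.items():
        if name in exclude:
            continue
        members = frozenset(members) & universe
        k = len(query & members)
        if k == 0:
            continue
        p = fisher_right_tail(k, len(query), len(members), len(universe))
        rows.append((name, k, len(query), len(members), len(universe), p))
    df = pd.DataFrame(rows, columns=["function", "k", "n", "K", "N", "p"])
    df = df.sort_values(by=["p", "k", "function"],
                        ascending=[True, False, True]).reset_index(drop=True)
    if fdr and len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def rank_shift(before: pd.DataFrame, after: pd.DataFrame) -> pd.DataFrame:
    """Per-function rank movement between two enrichment rankings.

    ``shift = rank_before - rank_after`` (positive when the function moved
    up).  Functions present in only one ranking are kept with a missing
    shift and ``in_both = False``.
    """
    b = before.set_index("function")["rank"]
    a = after.set_index("function")["rank"]
    names = list(dict.fromkeys(list(b.index) + list(a.index)))
    rows = []
    for name in names:
        rb = int(b[name]) if name in b.index else None
        ra = int(a[name]) if name in a.index else None
        rows.append({
            "function": name,
            "rank_before": np.nan if rb is None else rb,
            "rank_after": np.nan if ra is None else ra,
            "shift": (rb - ra) if rb is not None and ra is not None else np.nan,
            "in_both": rb is not None and ra is not None,
        })
    return pd.DataFrame(rows)


@dataclass
class TierCrossReference:
    """Annotation membership of a hierarchy, tier by tier."""

    per_tier: pd.DataFrame          # tier, members, count, frac_up, frac_down
    total_annotated: int
    top_two_count: int              # annotated genes in primary+secondary
    top_two_size: int               # all genes in primary+secondary
    frac_up: float                  # among all annotated hierarchy genes
    frac_down: float


def cross_reference_tiers(gih: pd.DataFrame, annotation) -> TierCrossReference:
    """Cross-reference a hierarchy table with one annotation gene set.

    ``gih`` needs columns gene, tier, signed_fc (the published-table
    loaders use ``fold_change``, accepted as an alias).  Up/down fractions
    are computed from the sign of the fold change.
    """
    fc_col = "signed_fc" if "signed_fc" in gih.columns else "fold_change"
    annotation = frozenset(normalize_symbol(g) for g in annotation)
    rows = []
    annotated_all = gih[gih["gene"].map(normalize_symbol).isin(annotation)]
    for tier in ("primary", "secondary", "peripheral", "orphan"):
        sub = annotated_all[annotated_all["tier"] == tier]
        n = len(sub)
        up = int((sub[fc_col] > 0).sum())
        down = int((sub[fc_col] < 0).sum())
        rows.append({
            "tier": tier,
            "members": sorted(sub["gene"]),
            "count": n,
            "frac_up": up / n if n else 0.0,
            "frac_down": down / n if n else 0.0,
        })
    per_tier = pd.DataFrame(rows)
    top_two = gih[gih["tier"].isin(["primary", "secondary"])]
    top_two_hits = annotated_all[annotated_all["tier"].isin(
        ["primary", "secondary"])]
    n_all = len(annotated_all)
    return TierCrossReference(
        per_tier=per_tier,
        total_annotated=n_all,
        top_two_count=len(top_two_hits),
        top_two_size=len(top_two),
        frac_up=float((annotated_all[fc_col] > 0).sum() / n_all) if n_all else 0.0,
        frac_down=float((annotated_all[fc_col] < 0).sum() / n_all) if n_all else 0.0,
    )
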