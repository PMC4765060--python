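"""Assembly of genes of interest (GOI) with per-source overlap accounting.

The GOI for a side are built up from an initial seed (the genes changed
differently between sides), then a sequence of curated sources — a
canonical pathway's genes first, then per-network gene lists in network-ID
order.  Each source contributes its members restricted to the side's
candidate pool; accounting records, per source, how many of its
contributed genes were already collected (``overlap_with_previous``) and
how many are new (``net_new``).  The final gene set is order-independent;
only the accounting depends on source order.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core_io import CONTRA, IPSI, InputError, normalize_symbol
from .bilateral import COMMON_DIFFERENT, UNIQUE_CONTRA, UNIQUE_IPSI

__all__ = ["GOISource", "GOISet", "candidate_pool", "assemble_goi"]


@dataclass(frozen=True)
class GOISource:
    """One ordered source of candidate genes of interest."""

    name: str
    members: tuple[str, ...]

    @classmethod
    def from_genes(cls, name: str, genes) -> "GOISource":
        members = tuple(dict.fromkeys(normalize_symbol(g) for g in genes))
        if not members:
            raise InputError(f"source {name!r} has no members")
        return cls(name=name, members=members)


@dataclass
class GOISet:
    """Assembled genes of interest with provenance and accounting.

    ``provenance`` maps each gene to the ordered list of source names that
    contributed it (``"seed"`` first where applicable); ``accounting`` has
    one row per source with total_found / overlap_with_previous / net_new.
    """

    side: str
    genes: frozenset[str]
    provenance: dict[str, list[str]] = field(default_factory=dict)
    accounting: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["source", "total_found", "overlap_with_previous",
                     "net_new"]))

    def __len__(self) -> int:
        return len(self.genes)


def candidate_pool(bilateral_table: pd.DataFrame, side: str) -> frozenset[str]:
    """Candidate GOI pool for a side: that side's uniquely-changed genes
    plus every gene that changed differently on the two sides."""
    if side == IPSI:
        unique = UNIQUE_IPSI
    elif side == CONTRA:
        unique = UNIQUE_CONTRA
    else:
        raise InputError(f"unknown side {side!r}")
    keep = bilateral_table["partition"].isin([unique, COMMON_DIFFERENT])
    return frozenset(bilateral_table.loc[keep, "gene"])


def assemble_goi(seed, sources: list[GOISource], side: str = IPSI,
                 pool: frozenset[str] | None = None) -> GOISet:
    """Assemble a GOI set from a seed and ordered sources.

    Each source contributes ``members ∩ pool`` (all members when ``pool``
    is None, i.e. when the source lists are already the overlap with the
    candidate genes).  Accounting is computed against the running union,
    seed first, so ``overlap_with_previous + net_new == total_found`` for
    every source and the net contributions plus the seed size sum to the
    final set size.
    """
    seed = frozenset(normalize_symbol(g) for g in seed)
    collected = set(seed)
    provenance = {g: ["seed"] for g in sorted(seed)}
    rows = []
    for src in sources:
        found = [g for g in src.members
                 if pool is None or g in pool]
        overlap = sum(1 for g in found if g in collected)
        net = len(found) - overlap
        rows.append((src.name, len(found), overlap, net))
        for g in found:
            sources_of_g = provenance.setdefault(g, [])
            if src.name not in sources_of_g:
                sources_of_g.append(src.name)
        collected.update(found)
    accounting = pd.DataFrame(
        rows, columns=["source", "total_found", "overlap_with_previous",
                       "net_new"])
    return GOISet(side=side, genes=frozenset(collected),
                  provenance=provenance, accounting=accounting)
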