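"""Bundled reference tables from the rat unilateral-TBI cell-death study.

These small plain-text tables are the printed results the pipeline was
designed around: the 73 genes that changed differently between brain
sides (with their signed fold changes and ratios), the apoptosis-signaling
pathway genes of interest found per side, the per-network genes of
interest, the two published gene interaction hierarchies (gene, fold
change, tier), and the cell-cycle annotation of each hierarchy.  They
serve as regression fixtures and as worked-example inputs; they are not
required for analyzing user data.

Sides are ``"ipsi"`` and ``"contra"`` matching the ipsilateral-vs-naive
and contralateral-vs-naive comparisons.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_changed_differently",
    "load_apoptosis_pathway_goi",
    "load_network_goi",
    "load_hierarchy",
    "load_cell_cycle_genes",
]

_SIDES = ("ipsi", "contra")


def _path(name: str):
    return resources.files("bigih.data").joinpath(name)


def _check_side(side: str) -> str:
    if side not in _SIDES:
        raise ValueError(f"side must be one of {_SIDES}, got {side!r}")
    return side


def load_changed_differently() -> pd.DataFrame:
    """The 73 genes changed on both sides with |ratio| > 2.

    Columns: gene, fold_change_ipsi, fold_change_contra, ratio (as
    printed, 3 decimals), compartment.
    """
    with resources.as_file(_path("changed_differently.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_apoptosis_pathway_goi(side: str) -> list[str]:
    """Apoptosis-signaling canonical-pathway genes of interest per side."""
    _check_side(side)
    text = _path(f"apoptosis_goi_{side}.txt").read_text()
    return text.split()


def load_network_goi(side: str) -> dict[int, list[str]]:
    """Genes of interest found in each of the top 6 curated networks.

    Returns ``{network_id: [gene, ...]}`` in network-ID order.
    """
    _check_side(side)
    with resources.as_file(_path(f"network_goi_{side}.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return {int(nid): list(sub["gene"])
            for nid, sub in df.groupby("network_id", sort=True)}


def load_hierarchy(side: str) -> pd.DataFrame:
    """Published gene interaction hierarchy for one side.

    Columns: gene, fold_change, tier (primary | secondary | peripheral |
    orphan), compartment.
    """
    _check_side(side)
    with resources.as_file(_path(f"hierarchy_{side}.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_cell_cycle_genes(side: str) -> list[str]:
    """Hierarchy genes annotated to the cell-cycle biological function."""
    _check_side(side)
    return _path(f"cell_cycle_{side}.txt").read_text().split()
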