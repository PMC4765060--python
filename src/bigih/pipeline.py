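"""End-to-end convenience driver: expression → selection → bilateral
partition → GOI → hierarchy → enrichment."""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import bilateral as _bilateral
from . import enrichment as _enrichment
from . import expression_prep as _prep
from . import gih as _gih
from . import goi_assembly as _goi
from .core_io import CONTRA, IPSI, AnalysisConfig, ExpressionMatrix, GeneSetCollection

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """All intermediate and final tables of one pipeline run."""

    selection: dict[str, pd.DataFrame]
    bilateral_table: pd.DataFrame
    summary: dict
    goi: dict[str, _goi.GOISet]
    hierarchy: dict[str, pd.DataFrame] = field(default_factory=dict)
    enrichment: dict[str, pd.DataFrame] = field(default_factory=dict)


def run_pipeline(expr: ExpressionMatrix,
                 calls: pd.DataFrame | None = None,
                 interactions: set | None = None,
                 annotations: GeneSetCollection | None = None,
                 goi_sources: dict[str, list[_goi.GOISource]] | None = None,
                 config: AnalysisConfig | None = None) -> PipelineResult:
    """Run selection, partition, GOI assembly and (where inputs allow)
    hierarchy and enrichment for both sides.

    ``goi_sources`` maps side name to the ordered curated sources for that
    side; when absent, the GOI are the candidate pool itself (unique
    genes plus changed-differently genes).  Hierarchy requires
    ``interactions``; enrichment requires ``annotations`` as well.
    """
    config = config or AnalysisConfig()
    selection = _prep.select_changed_genes(expr, calls, config)
    table = _bilateral.build_bilateral_table(
        selection[IPSI], selection[CONTRA], config.ratio_cutoff)
    summary = _bilateral.partition_summary(table).as_dict()

    fold_changes = {
        IPSI: dict(zip(selection[IPSI]["gene"], selection[IPSI]["signed_fc"])),
        CONTRA: dict(zip(selection[CONTRA]["gene"],
                         selection[CONTRA]["signed_fc"])),
    }

    goi: dict[str, _goi.GOISet] = {}
    hierarchy: dict[str, pd.DataFrame] = {}
    enrich: dict[str, pd.DataFrame] = {}
    for side in (IPSI, CONTRA):
        pool = _goi.candidate_pool(table, side)
        sources = (goi_sources or {}).get(side, [])
        goi[side] = _goi.assemble_goi(pool if not sources else
                                      _seed_for(table, side),
                                      sources, side=side, pool=pool or None)
        if interactions is not None and goi[side].genes:
            hierarchy[side] = _gih.build_hierarchy(
                goi[side].genes, interactions, config,
                fold_changes=fold_changes[side])
            if annotations is not None:
                top2 = hierarchy[side][hierarchy[side]["tier"].isin(
                    ["primary", "secondary"])]["gene"]
                universe = expr.genes
                enrich[side + "_goi"] = _enrichment.rank_functions(
                    goi[side].genes, annotations, universe)
                enrich[side + "_top2"] = _enrichment.rank_functions(
                    top2, annotations, universe)
    return PipelineResult(selection=selection, bilateral_table=table,
                          summary=summary, goi=goi, hierarchy=hierarchy,
                          enrichment=enrich)


def _seed_for(table: pd.DataFrame, side: str) -> frozenset[str]:
    """Seed of a curated-source GOI assembly: the changed-differently genes."""
    keep = table["partition"] == _bilateral.COMMON_DIFFERENT
    return frozenset(table.loc[keep, "gene"])
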