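"""Ipsilateral/contralateral ratio and the four-way bilateral partition.

Genes passing the fold-change and presence rules on at least one side of
the brain are partitioned into

* ``unique_ipsi`` / ``unique_contra`` — changed on one side only;
* ``common_similar`` — changed on both sides with |ratio| <= cutoff;
* ``common_different`` — changed on both sides with |ratio| > cutoff.

The ratio compares relative expression between sides on a linear scale.
Writing ``lin(f)`` for the signed fold change mapped back to a plain
ratio (``f`` if positive, ``1/|f|`` if negative), the bilateral ratio of
a pair ``(f_i, f_c)`` is

    r = lin(f_i) / lin(f_c);   ratio = r if r >= 1 else -1/r

so |ratio| >= 1 always and the sign is negative exactly when relative
expression is lower ipsilaterally than contralaterally.  On each of the
five sign/order regimes a piecewise formulation distinguishes, this
single rule reduces to the corresponding piecewise formula; it also
covers the remaining regime (increased on both sides, contralateral
larger) by symmetry, which the piecewise list omits — such rows are
flagged as extrapolated.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import CONTRA, IPSI, InputError

__all__ = [
    "linearize",
    "bilateral_ratio",
    "classify_gene",
    "build_bilateral_table",
    "partition_summary",
    "PARTITIONS",
]

UNIQUE_IPSI = "unique_ipsi"
UNIQUE_CONTRA = "unique_contra"
COMMON_SIMILAR = "common_similar"
COMMON_DIFFERENT = "common_different"
PARTITIONS = (UNIQUE_IPSI, UNIQUE_CONTRA, COMMON_SIMILAR, COMMON_DIFFERENT)


def linearize(fc: float) -> float:
    """Map a signed fold change to a plain positive expression ratio."""
    if abs(fc) < 1:
        raise InputError(f"|signed fold change| must be >= 1, got {fc}")
    return fc if fc > 0 else 1.0 / abs(fc)


def bilateral_ratio(fc_i: float, fc_c: float) -> float:
    """Signed ratio of ipsilateral to contralateral relative expression."""
    r = linearize(fc_i) / linearize(fc_c)
    return r if r >= 1 else -1.0 / r


def is_extrapolated(fc_i: float, fc_c: float) -> bool:
    """True for the regime not covered by the piecewise formulation:
    increased on both sides with the contralateral change the larger."""
    return fc_i > 0 and fc_c > 0 and fc_c > fc_i


def classify_gene(fc_i: float | None, fc_c: float | None,
                  ratio_cutoff: float = 2.0) -> str:
    """Partition label for a gene from its per-side signed fold changes.

    ``None`` marks a side on which the gene did not pass selection; at
    least one side must be defined.  ``common_different`` requires
    |ratio| strictly greater than the cutoff.
    """
    if fc_i is None and fc_c is None:
        raise InputError("gene passed selection on neither side")
    if fc_c is None:
        return UNIQUE_IPSI
    if fc_i is None:
        return UNIQUE_CONTRA
    return (COMMON_DIFFERENT
            if abs(bilateral_ratio(fc_i, fc_c)) > ratio_cutoff
            else COMMON_SIMILAR)


def build_bilateral_table(de_ipsi: pd.DataFrame, de_contra: pd.DataFrame,
                          ratio_cutoff: float = 2.0) -> pd.DataFrame:
    """Join the two per-side changed-gene tables into one bilateral table.

    Inputs are the per-side selections (columns gene, signed_fc).  The
    output has one row per gene with columns gene, fc_ipsi, fc_contra,
    ratio (NaN unless both sides changed), partition, direction_ipsi,
    direction_contra, extrapolated.
    """
    fi = de_ipsi.set_index("gene")["signed_fc"] if len(de_ipsi) else pd.Series(dtype=float)
    fc = de_contra.set_index("gene")["signed_fc"] if len(de_contra) else pd.Series(dtype=float)
    rows = []
    for gene in sorted(set(fi.index) | set(fc.index)):
        a = float(fi[gene]) if gene in fi.index else None
        b = float(fc[gene]) if gene in fc.index else None
        ratio = bilateral_ratio(a, b) if a is not None and b is not None else np.nan
        rows.append({
            "gene": gene,
            "fc_ipsi": np.nan if a is None else a,
            "fc_contra": np.nan if b is None else b,
            "ratio": ratio,
            "partition": classify_gene(a, b, ratio_cutoff),
            "direction_ipsi": _direction(a),
            "direction_contra": _direction(b),
            "extrapolated": (a is not None and b is not None
                             and is_extrapolated(a, b)),
        })
    return pd.DataFrame(rows, columns=["gene", "fc_ipsi", "fc_contra", "ratio",
                                       "partition", "direction_ipsi",
                                       "direction_contra", "extrapolated"])


def _direction(fc: float | None) -> str:
    if fc is None:
        return "none"
    return "up" if fc > 0 else "down"


@dataclass
class PartitionSummary:
    """Counts and integer percentages per partition cell and direction."""

    counts: dict
    total: int

    def as_dict(self) -> dict:
        return {"total": self.total, **self.counts}


def partition_summary(table: pd.DataFrame) -> PartitionSummary:
    """Summarize a classified bilateral table.

    For each partition cell: count, up/down counts on the side that
    defines the cell (ipsilateral for unique_ipsi and the common cells,
    contralateral for unique_contra), and integer percentages of the cell
    total.  For ``common_different`` the number of negative-ratio genes is
    reported as well.
    """
    counts: dict = {}
    for part in PARTITIONS:
        sub = table[table["partition"] == part]
        side_col = ("direction_contra" if part == UNIQUE_CONTRA
                    else "direction_ipsi")
        n = len(sub)
        up = int((sub[side_col] == "up").sum())
        down = int((sub[side_col] == "down").sum())
        cell = {
            "count": n,
            "up": up,
            "down": down,
            "pct_up": int(round(100 * up / n)) if n else 0,
            "pct_down": int(round(100 * down / n)) if n else 0,
        }
        if part == COMMON_DIFFERENT:
            cell["negative_ratio"] = int((sub["ratio"] < 0).sum())
        counts[part] = cell
    return PartitionSummary(counts=counts, total=len(table))
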