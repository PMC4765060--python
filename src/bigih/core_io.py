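"""Readers, writers, symbol normalization and run configuration.

Gene identity throughout the package is the uppercased, whitespace-trimmed
gene symbol with any parenthesized alias annotation removed (``"CDK1
(Cdc2)"`` and ``"cdk1"`` both map to ``CDK1``).  No alias or orthology
resolution is attempted: the analysis operates on symbol-keyed tables and
mapping through external databases is out of scope.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "GROUPS",
    "IPSI",
    "CONTRA",
    "NAIVE",
    "AnalysisConfig",
    "ExpressionMatrix",
    "GeneSetCollection",
    "normalize_symbol",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
]

IPSI = "ipsilateral"
CONTRA = "contralateral"
NAIVE = "naive"
GROUPS = (IPSI, CONTRA, NAIVE)

_PAREN = re.compile(r"\s*\([^)]*\)\s*$")


class InputError(ValueError):
    """Malformed user input (file contents or arguments)."""


class ConfigError(ValueError):
    """Inconsistent configuration."""


def normalize_symbol(raw: str) -> str:
    """Normalize a raw gene symbol to its canonical uppercase form.

    Trailing parenthesized annotations (pathway aliases such as
    ``"CDK1 (Cdc2)"``) are removed before case folding.  Normalization is
    idempotent.
    """
    if raw is None:
        raise InputError("gene symbol is missing")
    s = _PAREN.sub("", str(raw).strip())
    s = s.strip()
    if not s:
        raise InputError(f"empty gene symbol: {raw!r}")
    return s.upper()


def normalize_symbols(raw: Iterable[str]) -> list[str]:
    return [normalize_symbol(s) for s in raw]


# --------------------------------------------------------------------------
# expression matrices
# --------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values with a group tag per sample.

    ``values`` is a DataFrame indexed by normalized gene symbol with one
    column per sample; ``groups`` maps every sample label to one of
    ``ipsilateral | contralateral | naive``.
    """

    values: pd.DataFrame
    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise InputError(f"duplicate gene rows: {list(dups)}")
        if self.values.columns.duplicated().any():
            raise InputError("duplicate sample labels")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ConfigError(f"samples missing from group map: {missing}")
        bad = {s: g for s, g in self.groups.items() if g not in GROUPS}
        if bad:
            raise ConfigError(f"unknown group tags: {bad}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def group_mean(self, group: str) -> pd.Series:
        cols = self.samples_in(group)
        if not cols:
            raise ConfigError(f"no samples in group {group!r}")
        return self.values[cols].mean(axis=1)


def read_expression_tsv(path, group_map: Mapping[str, str]) -> ExpressionMatrix:
    """Read a gene-by-sample TSV (first column gene symbol, header row).

    Gene symbols are normalized; duplicate gene rows are collapsed by
    arithmetic mean with a warning.  Non-numeric cells raise an error that
    names the offending row and column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise InputError(f"{path}: expected gene column plus ≥1 sample column")
    gene_col = df.columns[0]
    genes = [normalize_symbol(g) for g in df[gene_col]]
    data = df.drop(columns=[gene_col])
    for col in data.columns:
        converted = pd.to_numeric(data[col], errors="coerce")
        bad = converted.isna() & data[col].notna()
        if bad.any() or data[col].isna().any():
            row = int(bad.idxmax() if bad.any() else data[col].isna().idxmax())
            raise InputError(
                f"{path}: non-numeric value {df[col][row]!r} for gene "
                f"{genes[row]!r} in column {col!r}"
            )
        data[col] = converted
    data.index = pd.Index(genes, name="gene")
    if data.index.duplicated().any():
        dups = sorted(data.index[data.index.duplicated()].unique())
        warnings.warn(
            f"{len(dups)} duplicated gene symbol(s) collapsed by mean: "
            f"{dups[:5]}{'...' if len(dups) > 5 else ''}"
        )
        data = data.groupby(level=0, sort=False).mean()
    groups = {s: group_map[s] for s in data.columns if s in group_map}
    missing = [s for s in data.columns if s not in group_map]
    if missing:
        raise ConfigError(f"{path}: samples missing from group map: {missing}")
    return ExpressionMatrix(values=data, groups=groups)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


# --------------------------------------------------------------------------
# gene set collections (GMT)
# --------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets with optional per-set descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # names are unique by dict construction; emptiness checked here
        empty = [n for n, s in self.sets.items() if not s]
        if empty:
            raise InputError(f"empty gene sets: {empty}")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name, description, then members, tab-separated.

    Members are normalized and deduplicated within each line; a repeated
    set name is an error.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(
                    f"{path}:{lineno}: expected ≥3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc, *members = fields
            name = name.strip()
            if name in sets:
                raise InputError(f"{path}:{lineno}: duplicate set name {name!r}")
            norm = frozenset(normalize_symbol(m) for m in members if m.strip())
            if not norm:
                raise InputError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = norm
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# --------------------------------------------------------------------------
# interaction edge lists
# --------------------------------------------------------------------------

Edge = tuple[str, str]


def _as_edge(a: str, b: str) -> Edge:
    a, b = normalize_symbol(a), normalize_symbol(b)
    return (a, b) if a <= b else (b, a)


def read_edge_list(path) -> set[Edge]:
    """Read an undirected interaction edge list.

    Accepts two-column TSV/whitespace files (``A B``) and SIF lines
    (``A relation B``); the relation token is ignored.  Self-loops are
    dropped with a warning; duplicate and antiparallel pairs are stored
    once.
    """
    edges: set[Edge] = set()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens or line.lstrip().startswith("#"):
                continue
            if len(tokens) == 2:
                a, b = tokens
            elif len(tokens) == 3:
                a, _, b = tokens  # SIF dialect: relation token ignored
            else:
                raise InputError(
                    f"{path}:{lineno}: expected 2 (TSV) or 3 (SIF) tokens, "
                    f"got {len(tokens)}"
                )
            a, b = normalize_symbol(a), normalize_symbol(b)
            if a == b:
                n_self += 1
                continue
            edges.add(_as_edge(a, b))
    if n_self:
        warnings.warn(f"{path}: dropped {n_self} self-loop(s)")
    return edges


def write_edge_list(edges: Iterable[Edge], path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(edges):
            fh.write(f"{a}\t{b}\n")


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Tunable parameters for the whole pipeline.

    fold_change_cutoff
        Minimum |signed fold change| for a gene to count as changed on a
        side (default 2, i.e. "2-fold or more").
    ratio_cutoff
        |ipsilateral/contralateral ratio| above which a gene changing on
        both sides counts as changed *differently* (default 2, strict).
    presence_rule
        ``"either_side_all"`` (default): the gene must be called present in
        all injured-side samples of at least one side; ``"none"`` disables
        the presence gate.
    tier_primary_fraction / tier_secondary_fraction
        Degree thresholds for the interaction hierarchy, as fractions of
        the main-component size minus one (defaults 0.10 / 0.05).
    tau, alpha1, alpha2
        Detection-call parameters (discrimination-score offset and the two
        p-value thresholds); defaults follow common single-array detection
        practice and are fully configurable.
    """

    fold_change_cutoff: float = 2.0
    ratio_cutoff: float = 2.0
    presence_rule: str = "either_side_all"
    tier_primary_fraction: float = 0.10
    tier_secondary_fraction: float = 0.05
    tau: float = 0.015
    alpha1: float = 0.04
    alpha2: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fold_change_cutoff <= 1 or self.ratio_cutoff <= 1:
            raise ConfigError("cutoffs must be > 1")
        if not (0 < self.tier_secondary_fraction
                < self.tier_primary_fraction < 1):
            raise ConfigError(
                "need 0 < secondary_fraction < primary_fraction < 1")
        if not (0 < self.alpha1 < self.alpha2 < 1):
            raise ConfigError("need 0 < alpha1 < alpha2 < 1")
        if self.presence_rule not in ("either_side_all", "none"):
            raise ConfigError(f"unknown presence rule {self.presence_rule!r}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)
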