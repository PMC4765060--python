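"""Synthetic bilateral expression experiments, interaction networks and
annotation sets.

The generator emulates the statistical structure the pipeline assumes,
so every stage is testable without external data:

* a three-group design (ipsilateral, contralateral, naive; 3 replicates
  each) with log-normal baseline intensities and multiplicative
  log-normal replicate noise;
* side-biased differential expression — by default 18 % of genes change
  uniquely ipsilaterally (88 % of them up), 6.8 % uniquely
  contralaterally (75 % down), and 20 % on both sides, of which 82 %
  change similarly — with fold-change magnitudes log-uniform on [2, 40];
* an interaction network built by preferential attachment over the genes
  of interest plus background genes, with planted hubs wired to a fixed
  fraction of the GOI so their induced degree clears the primary-tier
  cutoff by a comfortable margin;
* annotation sets of random membership plus one focal set enriched among
  the planted hubs.

All randomness flows from a single root seed fanned out per sub-generator
through ``numpy`` seed sequences, so runs are reproducible bit for bit.
Detection calls are emitted directly (present unless dropped out);
probe-level simulation is not modeled here — the detection stage has its
own unit-level inputs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .bilateral import classify_gene
from .core_io import CONTRA, IPSI, NAIVE, ConfigError, ExpressionMatrix, GeneSetCollection

__all__ = ["SimulationParams", "GroundTruth", "simulate_expression",
           "simulate_network", "simulate_annotations"]


@dataclass
class SimulationParams:
    """Knobs of the synthetic experiment; defaults match the study design
    the pipeline targets (sample sizes, side biases, effect-size range)."""

    n_genes: int = 2000
    replicates: int = 3
    frac_unique_ipsi: float = 0.18
    frac_unique_contra: float = 0.068
    frac_common: float = 0.20
    p_up_unique_ipsi: float = 0.88
    p_up_unique_contra: float = 0.25
    p_common_similar: float = 0.82
    p_up_common_similar: float = 0.73
    p_negative_ratio_different: float = 0.04
    fc_low: float = 2.0
    fc_high: float = 40.0
    noise_sigma: float = 0.05
    dropout: float = 0.0
    baseline_log_mean: float = math.log(500.0)
    baseline_log_sigma: float = 1.0
    # network model
    n_background: int = 300
    attachment_m: int = 2
    n_hubs: int = 3
    hub_degree_fraction: float = 0.25
    # annotation model
    n_annotation_sets: int = 12
    annotation_set_size: tuple[int, int] = (15, 40)
    hub_enrichment: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.frac_unique_ipsi + self.frac_unique_contra + self.frac_common
        fracs = (self.frac_unique_ipsi, self.frac_unique_contra,
                 self.frac_common, self.p_up_unique_ipsi,
                 self.p_up_unique_contra, self.p_common_similar,
                 self.p_up_common_similar, self.p_negative_ratio_different,
                 self.dropout, self.hub_enrichment)
        if any(not 0 <= f <= 1 for f in fracs):
            raise ConfigError("all fractions must lie in [0, 1]")
        if total > 1:
            raise ConfigError(f"DE fractions sum to {total} > 1")
        if self.n_genes <= 0 or self.replicates <= 0:
            raise ConfigError("counts must be positive")
        if not 1 < self.fc_low < self.fc_high:
            raise ConfigError("need 1 < fc_low < fc_high")


@dataclass
class GroundTruth:
    """Per-gene truth emitted alongside the synthetic matrices."""

    table: pd.DataFrame       # gene, partition, fc_ipsi, fc_contra
    hubs: list[str] = field(default_factory=list)
    focal_annotation: str = ""

    def to_json_dict(self) -> dict:
        return {
            "hubs": self.hubs,
            "focal_annotation": self.focal_annotation,
            "genes": self.table.to_dict(orient="records"),
        }


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


def _log_uniform(rng, low, high, size=None):
    return np.exp(rng.uniform(math.log(low), math.log(high), size))


def _draw_fc(rng, params: SimulationParams, up: bool) -> float:
    m = float(_log_uniform(rng, params.fc_low, params.fc_high))
    return m if up else -m


def _lin(fc: float) -> float:
    return fc if fc > 0 else 1.0 / abs(fc)


def _draw_common_pair(rng, params: SimulationParams) -> tuple[float, float]:
    """A (fc_ipsi, fc_contra) pair for a gene changed on both sides."""
    if rng.random() < params.p_common_similar:
        up = rng.random() < params.p_up_common_similar
        fc_i = _draw_fc(rng, params, up)
        jitter = float(_log_uniform(rng, 1 / 1.8, 1.8))
        m_c = max(abs(fc_i) * jitter, params.fc_low)
        return fc_i, (m_c if up else -m_c)
    # changed differently: |ratio| > 2, usually higher ipsilaterally
    negative = rng.random() < params.p_negative_ratio_different
    ratio = float(_log_uniform(rng, 2.2, 25.0))
    subtype = rng.integers(3)
    if subtype == 0:          # both up, ipsi larger
        m_c = float(_log_uniform(rng, params.fc_low, 6.0))
        pair = (min(m_c * ratio, 80.0), m_c)
    elif subtype == 1:        # both down, contra more suppressed
        m_i = float(_log_uniform(rng, params.fc_low, 6.0))
        pair = (-m_i, -min(m_i * ratio, 80.0))
    else:                     # up ipsilaterally, down contralaterally
        m_i = float(_log_uniform(rng, params.fc_low, 10.0))
        m_c = ratio / m_i
        m_c = max(m_c, params.fc_low)
        pair = (m_i, -m_c)
    return (pair[1], pair[0]) if negative else pair


def simulate_expression(params: SimulationParams | None = None,
                        seed: int | None = None
                        ) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Simulate the gene-by-sample matrix, detection calls and truth."""
    params = params or SimulationParams()
    seed = params.seed if seed is None else seed
    rng_assign, rng_fc, rng_base, rng_noise, rng_drop = _rngs(seed, 5)

    genes = [f"G{i:05d}" for i in range(params.n_genes)]
    n = params.n_genes
    n_ui = int(round(params.frac_unique_ipsi * n))
    n_uc = int(round(params.frac_unique_contra * n))
    n_co = int(round(params.frac_common * n))
    perm = rng_assign.permutation(n)
    idx_ui = set(perm[:n_ui])
    idx_uc = set(perm[n_ui:n_ui + n_uc])
    idx_co = set(perm[n_ui + n_uc:n_ui + n_uc + n_co])

    fc_i = np.ones(n)
    fc_c = np.ones(n)
    partitions = []
    for i in range(n):
        if i in idx_ui:
            fc_i[i] = _draw_fc(rng_fc, params,
                               rng_fc.random() < params.p_up_unique_ipsi)
            partitions.append(classify_gene(fc_i[i], None))
        elif i in idx_uc:
            fc_c[i] = _draw_fc(rng_fc, params,
                               rng_fc.random() < params.p_up_unique_contra)
            partitions.append(classify_gene(None, fc_c[i]))
        elif i in idx_co:
            fc_i[i], fc_c[i] = _draw_common_pair(rng_fc, params)
            partitions.append(classify_gene(fc_i[i], fc_c[i]))
        else:
            partitions.append("unchanged")

    baseline = np.exp(rng_base.normal(params.baseline_log_mean,
                                      params.baseline_log_sigma, n))
    lin_i = np.array([_lin(f) for f in fc_i])
    lin_c = np.array([_lin(f) for f in fc_c])
    group_means = {IPSI: baseline * lin_i, CONTRA: baseline * lin_c,
                   NAIVE: baseline}

    columns, data = [], []
    for group in (IPSI, CONTRA, NAIVE):
        for r in range(params.replicates):
            label = f"{group[:5]}_{r + 1}"
            noise = (np.exp(rng_noise.normal(0.0, params.noise_sigma, n))
                     if params.noise_sigma > 0 else np.ones(n))
            columns.append(label)
            data.append(group_means[group] * noise)
    values = pd.DataFrame(np.column_stack(data), index=pd.Index(genes, name="gene"),
                          columns=columns)
    groups = {f"{g[:5]}_{r + 1}": g for g in (IPSI, CONTRA, NAIVE)
              for r in range(params.replicates)}
    matrix = ExpressionMatrix(values=values, groups=groups)

    call_rows = []
    for sample in columns:
        dropped = (rng_drop.random(n) < params.dropout
                   if params.dropout > 0 else np.zeros(n, dtype=bool))
        for i, gene in enumerate(genes):
            call_rows.append((gene, sample,
                              "absent" if dropped[i] else "present", 0.0))
    calls = pd.DataFrame(call_rows, columns=["gene", "sample", "call", "p"])

    truth_table = pd.DataFrame({
        "gene": genes,
        "partition": partitions,
        "fc_ipsi": fc_i,
        "fc_contra": fc_c,
    })
    return matrix, calls, GroundTruth(table=truth_table)


def simulate_network(params: SimulationParams | None = None,
                     goi=None, seed: int | None = None
                     ) -> tuple[set, list[str]]:
    """Preferential-attachment interaction network with planted hubs.

    Returns the undirected edge set over GOI plus background genes and
    the list of planted hub genes.  Each hub is wired to
    ``hub_degree_fraction`` of the other GOI, placing its induced degree
    well above the primary-tier cutoff (which is one tenth of the main
    component size).
    """
    import networkx as nx

    params = params or SimulationParams()
    seed = params.seed if seed is None else seed
    rng_graph, rng_hub = _rngs(seed, 2)

    goi = sorted(goi) if goi is not None else [f"G{i:05d}" for i in range(160)]
    if params.n_hubs > len(goi):
        raise ConfigError(f"{params.n_hubs} hubs requested for {len(goi)} GOI")
    background = [f"BG{i:05d}" for i in range(params.n_background)]
    nodes = list(goi) + background
    order = rng_graph.permutation(len(nodes))

    edges: set = set()
    if params.attachment_m > 0 and len(nodes) > params.attachment_m:
        g = nx.barabasi_albert_graph(
            len(nodes), params.attachment_m,
            seed=np.random.RandomState(int(rng_graph.integers(2**31 - 1))))
        for a, b in g.edges:
            u, v = nodes[order[a]], nodes[order[b]]
            if u != v:
                edges.add((u, v) if u <= v else (v, u))

    hubs = list(rng_hub.choice(goi, size=params.n_hubs, replace=False)) \
        if params.n_hubs else []
    k = int(round(params.hub_degree_fraction * (len(goi) - 1)))
    for hub in hubs:
        others = [g for g in goi if g != hub]
        targets = rng_hub.choice(others, size=min(k, len(others)),
                                 replace=False)
        for t in targets:
            edges.add((hub, t) if hub <= t else (t, hub))
    return edges, [str(h) for h in hubs]


def simulate_annotations(params: SimulationParams | None = None,
                         truth: GroundTruth | None = None,
                         universe=None, seed: int | None = None
                         ) -> GeneSetCollection:
    """Random annotation sets plus one hub-enriched focal set.

    With ``hub_enrichment = s``, each planted hub joins the focal set with
    probability ``s``; the rest of the focal set (and all background sets)
    is drawn uniformly from the universe.  ``s = 0`` leaves the focal set
    indistinguishable from background.
    """
    params = params or SimulationParams()
    seed = params.seed if seed is None else seed
    (rng,) = _rngs(seed, 1)
    hubs = list(truth.hubs) if truth is not None else []
    if universe is None:
        universe = [f"G{i:05d}" for i in range(params.n_genes)]
    universe = sorted(set(universe) | set(hubs))

    lo, hi = params.annotation_set_size
    sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    size = int(rng.integers(lo, hi + 1))
    focal = {h for h in hubs if rng.random() < params.hub_enrichment}
    fill = [g for g in universe if g not in focal]
    extra = rng.choice(fill, size=max(size - len(focal), 0), replace=False)
    sets["focal"] = frozenset(focal | set(map(str, extra)))
    descriptions["focal"] = "hub-enriched synthetic function"
    for i in range(params.n_annotation_sets - 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        sets[f"set{i + 1:02d}"] = frozenset(map(str, members))
        descriptions[f"set{i + 1:02d}"] = "background synthetic function"
    if truth is not None:
        truth.focal_annotation = "focal"
    return GeneSetCollection(sets=sets, descriptions=descriptions)
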