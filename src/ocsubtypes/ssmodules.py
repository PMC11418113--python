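"""Subtype-specific coexpression module selection by hypergeometric overlap.

Module detection itself (e.g. planar-filtered-network multiscale clustering)
is treated as a pluggable upstream step: any named gene-list table, with an
optional parent-child topology, can be supplied. This module tests each
candidate's overlap with a subtype's TT and TN gene sets and, within a
topology chain, keeps the most significant member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Set, Tuple

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .matrix import ValidationError


@dataclass
class ModuleSet:
    """Named gene lists with an optional acyclic parent-child hierarchy."""

    modules: Dict[str, Set[str]]
    universe: Set[str]
    parents: Dict[str, str] = field(default_factory=dict)  # child -> parent

    def __post_init__(self) -> None:
        for name, genes in self.modules.items():
            extra = genes - self.universe
            if extra:
                raise ValidationError(
                    f"module {name!r} has genes outside the universe: {sorted(extra)[:5]}"
                )
        g = nx.DiGraph((p, c) for c, p in self.parents.items())
        if not nx.is_directed_acyclic_graph(g):
            raise ValidationError("module hierarchy contains a cycle")


def module_overlap_test(
    module: Set[str], target: Set[str], universe: Set[str]
) -> float:
    """Upper-tail hypergeometric p-value P(X >= |module & target|).

    Population size |universe|, success states |target|, draws |module|.
    """
    if not module or not universe:
        raise ValidationError("module and universe must be non-empty")
    if not module <= universe or not target <= universe:
        raise ValidationError("module and target must be subsets of the universe")
    overlap = len(module & target)
    return float(hypergeom.sf(overlap - 1, len(universe), len(target), len(module)))


def select_ssmodules(
    modules: ModuleSet,
    tt: Set[str],
    tn: Set[str],
    alpha: float = 0.05,
    combine: str = "product",
) -> pd.DataFrame:
    """Select subtype-specific modules.

    A module qualifies when both its TT and TN overlap p-values are below
    ``alpha``. Within any connected topology chain, only the member with the
    smallest combined significance (p_TT * p_TN by default, min of the two
    with ``combine="min"``) is kept; ties go to the smaller module.

    Returns a table with one row per module: p_TT, p_TN, and whether it was
    selected.
    """
    rows = []
    for name in sorted(modules.modules):
        genes = modules.modules[name]
        p_tt = module_overlap_test(genes, tt, modules.universe)
        p_tn = module_overlap_test(genes, tn, modules.universe)
        rows.append({"module": name, "p_tt": p_tt, "p_tn": p_tn,
                     "size": len(genes)})
    table = pd.DataFrame(rows).set_index("module")
    passing = set(table.index[(table["p_tt"] < alpha) & (table["p_tn"] < alpha)])

    # group passing modules by connected component of the hierarchy
    g = nx.Graph()
    g.add_nodes_from(modules.modules)
    g.add_edges_from((c, p) for c, p in modules.parents.items())

    def score(m: str) -> float:
        if combine == "min":
            return min(table.at[m, "p_tt"], table.at[m, "p_tn"])
        return table.at[m, "p_tt"] * table.at[m, "p_tn"]

    selected: Set[str] = set()
    for comp in nx.connected_components(g):
        cand = sorted(comp & passing)
        if not cand:
            continue
        best = min(cand, key=lambda m: (score(m), table.at[m, "size"], m))
        selected.add(best)
    table["selected"] = [m in selected for m in table.index]
    return table


def module_filter_inputs(
    nodes: pd.DataFrame,
    edges: pd.DataFrame,
    gene_weight_min: float = 5.5,
    edge_weight_min: float = 0.6,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Strict-inequality pre-filter on node and edge weights.

    ``nodes`` needs columns (gene, weight); ``edges`` (source, target,
    weight). Nodes at or below ``gene_weight_min`` and edges at or below
    ``edge_weight_min`` (or touching a removed node) are dropped.
    """
    kept_nodes = nodes[nodes["weight"] > gene_weight_min]
    keep = set(kept_nodes["gene"])
    kept_edges = edges[
        (edges["weight"] > edge_weight_min)
        & edges["source"].isin(keep)
        & edges["target"].isin(keep)
    ]
    return kept_nodes.reset_index(drop=True), kept_edges.reset_index(drop=True)
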