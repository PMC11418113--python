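"""Subtype scoring of malignant cells with bin-matched control gene sets.

A cell's subtype score SC(j) is the mean expression of the subtype signature
genes in that cell minus the mean expression of a control gene set drawn to
match the signature's overall expression distribution: all genes are ranked
by mean expression over cells and split into 30 equal bins (remainder to the
last bin); for every bin containing a signature gene, 100 genes are sampled
from that bin. Cells whose second-best subtype score is too strong are
flagged as hybrids and removed before subtype proportions are summarized.
"""

from __future__ import annotations

import math
from typing import Dict, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .degenes import differential_genes
from .matrix import ExpressionMatrix, ValidationError


def bin_genes(
    mean_expression: pd.Series, n_bins: int = 30
) -> pd.Series:
    """Map genes to expression bins.

    Genes are sorted by mean expression ascending (ties lexicographic by
    name) and split into ``n_bins`` bins of floor(G / n_bins) genes; any
    remainder goes to the last bin. Returns a Series gene -> bin (1-based).
    """
    g = len(mean_expression)
    if g < n_bins:
        raise ValidationError(f"{g} genes < {n_bins} bins")
    ordered = mean_expression.loc[sorted(mean_expression.index)].sort_values(
        kind="mergesort"
    )
    size = g // n_bins
    bins = np.minimum(np.arange(g) // size + 1, n_bins)
    return pd.Series(bins, index=ordered.index, name="bin")


def control_set(
    signature: Sequence[str],
    bin_map: pd.Series,
    per_bin: int = 100,
    seed: int = 0,
) -> Tuple[List[str], bool]:
    """Draw the bin-matched control gene multiset for one signature.

    For every bin containing at least one signature gene, ``per_bin`` genes
    are sampled uniformly from that bin — with replacement when the bin holds
    fewer than ``per_bin`` genes (the returned flag reports whether any bin
    needed replacement). The union over bins (a multiset when replacement was
    needed) mirrors the signature's expression distribution scaled up.
    """
    sig = [g for g in signature if g in bin_map.index]
    if not sig:
        raise ValidationError("signature is empty or absent from the bin map")
    rng = np.random.default_rng(seed)
    control: List[str] = []
    replaced = False
    sig_bins = sorted(set(bin_map.loc[sig]))
    for b in sig_bins:
        pool = sorted(bin_map.index[bin_map == b])
        replace = len(pool) < per_bin
        replaced = replaced or replace
        picks = rng.choice(pool, size=per_bin, replace=replace)
        control.extend(picks)
    return control, replaced


def subtype_score(
    cell_matrix: pd.DataFrame,
    signature: Sequence[str],
    control: Sequence[str],
) -> pd.Series:
    """SC per cell: mean signature expression minus mean control expression."""
    sig = [g for g in signature if g in cell_matrix.index]
    if not sig:
        raise ValidationError("no signature gene present in the cell matrix")
    ctrl = [g for g in control if g in cell_matrix.index]
    if not ctrl:
        raise ValidationError("no control gene present in the cell matrix")
    sig_mean = cell_matrix.loc[sig].mean(axis=0)
    ctrl_mean = cell_matrix.loc[ctrl].mean(axis=0)
    return sig_mean - ctrl_mean


def score_cells(
    cell_matrix: pd.DataFrame,
    signatures: Mapping[str, Sequence[str]],
    n_bins: int = 30,
    per_bin: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """SC scores of every cell against every subtype signature."""
    bins = bin_genes(cell_matrix.mean(axis=1), n_bins=n_bins)
    cols = {}
    for i, (s, sig) in enumerate(sorted(signatures.items())):
        ctrl, _ = control_set(sig, bins, per_bin=per_bin, seed=seed + i)
        cols[s] = subtype_score(cell_matrix, sig, ctrl)
    return pd.DataFrame(cols)


def assign_and_filter(
    scores: pd.DataFrame,
    t1: float = 1.0,
    t2: float = 0.3,
    t3: float = 0.1,
) -> pd.DataFrame:
    """Assign each cell to its top-scoring subtype and flag hybrids.

    A cell is a hybrid when ALL hold: the second-best score exceeds ``t1``;
    the gap between second and third scores exceeds ``t2``; and the second
    score exceeds ``t3`` times the top score. Hybrids keep their scores but
    are excluded from downstream proportion summaries. Ties at the top are
    resolved to the lexicographically first subtype and flagged.
    """
    subtypes = sorted(scores.columns)
    S = scores[subtypes].to_numpy(dtype=float)
    order = np.argsort(-S, axis=1, kind="stable")
    first = S[np.arange(len(S)), order[:, 0]]
    second = S[np.arange(len(S)), order[:, 1]] if len(subtypes) > 1 else np.full(len(S), -np.inf)
    third = S[np.arange(len(S)), order[:, 2]] if len(subtypes) > 2 else np.full(len(S), -np.inf)
    hybrid = (second > t1) & ((second - third) > t2) & (second > t3 * first)
    assigned = [subtypes[i] for i in order[:, 0]]
    tie = first == second
    out = scores.copy()
    out["assigned"] = assigned
    out["hybrid"] = hybrid
    out["tie"] = tie
    return out


def stage_proportions(
    assignments: pd.DataFrame, stages: pd.Series
) -> pd.DataFrame:
    """Subtype proportions per stage over retained (non-hybrid) cells."""
    keep = assignments.index[~assignments["hybrid"]]
    table = pd.crosstab(
        stages.loc[keep], assignments.loc[keep, "assigned"], normalize="index"
    )
    return table


def stage_de(
    cell_matrix: pd.DataFrame,
    stages: pd.Series,
    relapse: str = "relapse",
    primary: str = "primary",
    metastasis: str = "metastasis",
    lfc: float = 1.0,
    fdr: float = 0.05,
) -> Set[str]:
    """Genes commonly upregulated in relapse vs both primary and metastasis."""
    em = ExpressionMatrix(cell_matrix, pd.DataFrame(index=cell_matrix.columns))
    rel = stages.index[stages == relapse]
    pri = stages.index[stages == primary]
    met = stages.index[stages == metastasis]
    _, up_rp = differential_genes(em, rel, pri, lfc=lfc, fdr=fdr)
    _, up_rm = differential_genes(em, rel, met, lfc=lfc, fdr=fdr)
    return up_rp & up_rm
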