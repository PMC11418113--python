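"""Differential expression, F-scores, and subtype-specific signatures.

One moderated two-sample test serves both the subtype-vs-rest (TT) and the
subtype-vs-normal (TN) contrasts: the pooled per-gene variance is shrunk
50/50 toward the genewise-median variance before forming the t statistic,
a lightweight analogue of variance-moderated microarray testing. P-values
use the Student t distribution on the pooled degrees of freedom and are
BH-adjusted across genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix, ValidationError


@dataclass
class SubtypeSignature:
    """The four gene sets whose intersection defines a subtype signature."""

    subtype: str
    set1_tt: Set[str]
    set2_tn: Set[str]
    set3_cancer_fc: Set[str]
    set4_cancer_vs_normal_fc: Set[str]

    @property
    def genes(self) -> List[str]:
        inter = (
            self.set1_tt & self.set2_tn
            & self.set3_cancer_fc & self.set4_cancer_vs_normal_fc
        )
        return sorted(inter)


def differential_genes(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    lfc: float = 1.0,
    fdr: float = 0.05,
    shrink_weight: float = 0.5,
) -> Tuple[pd.DataFrame, Set[str]]:
    """Moderated two-group comparison; returns the DE table and the up set.

    The up set is {genes with log2FC > lfc (A over B) and BH FDR < fdr}.
    ``shrink_weight`` is the weight on the genewise-median variance in the
    pooled-variance shrinkage (0 recovers the ordinary t test).
    """
    a = pd.Index(group_a)
    b = pd.Index(group_b)
    if len(a.intersection(b)):
        raise ValidationError("groups overlap")
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("each group needs at least 3 samples")
    Xa = matrix.values[a].to_numpy()
    Xb = matrix.values[b].to_numpy()
    na, nb = Xa.shape[1], Xb.shape[1]
    mean_a, mean_b = Xa.mean(axis=1), Xb.mean(axis=1)
    logfc = mean_a - mean_b
    va = Xa.var(axis=1, ddof=1)
    vb = Xb.var(axis=1, ddof=1)
    df = na + nb - 2
    pooled = ((na - 1) * va + (nb - 1) * vb) / df
    target = np.median(pooled)
    s2 = (1 - shrink_weight) * pooled + shrink_weight * target
    se = np.sqrt(s2 * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    p = 2 * stats.t.sf(np.abs(t), df)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    table = pd.DataFrame(
        {"logFC": logfc, "t": t, "pvalue": p, "fdr": p_adj}, index=matrix.genes
    )
    up = set(table.index[(table["logFC"] > lfc) & (table["fdr"] < fdr)])
    return table, up


def tt_tn_sets(
    matrix: ExpressionMatrix,
    assignments: pd.Series,
    normal_samples: Sequence[str],
    lfc: float = 1.0,
    fdr: float = 0.05,
) -> Dict[str, Tuple[Set[str], Set[str]]]:
    """Per subtype: TT = up vs the union of other subtypes; TN = up vs normals."""
    normals = pd.Index(normal_samples)
    if len(normals) == 0:
        raise ValidationError("no normal samples supplied; TN sets undefined")
    out: Dict[str, Tuple[Set[str], Set[str]]] = {}
    for s in sorted(assignments.unique()):
        own = assignments.index[assignments == s]
        rest = assignments.index[assignments != s]
        _, tt = differential_genes(matrix, own, rest, lfc=lfc, fdr=fdr)
        _, tn = differential_genes(matrix, own, normals, lfc=lfc, fdr=fdr)
        out[s] = (tt, tn)
    return out


def f_scores(matrix: ExpressionMatrix, assignments: pd.Series) -> pd.Series:
    """One-way ANOVA F statistic per gene across the subtype groups.

    Genes with zero within-group variance but nonzero between-group variance
    have infinite F; they are reported as one more than the largest finite F
    so ranking remains usable.
    """
    groups = [assignments.index[assignments == s] for s in sorted(assignments.unique())]
    for g in groups:
        if len(g) < 2:
            raise ValidationError("every subtype group needs at least 2 samples")
    blocks = [matrix.values[g].to_numpy() for g in groups]
    n_total = sum(b.shape[1] for b in blocks)
    k = len(blocks)
    grand = matrix.values[[s for g in groups for s in g]].to_numpy().mean(axis=1)
    ss_between = sum(b.shape[1] * (b.mean(axis=1) - grand) ** 2 for b in blocks)
    ss_within = sum(((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for b in blocks)
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n_total - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(ms_within > 0, ms_between / ms_within, np.inf)
    F = np.where(ms_between == 0, 0.0, F)  # constant gene: F := 0
    finite_max = np.nanmax(np.where(np.isfinite(F), F, np.nan)) if np.isfinite(F).any() else 0.0
    F = np.where(np.isinf(F), finite_max + 1.0, F)
    return pd.Series(F, index=matrix.genes, name="F")


def subtype_signatures(
    tt_tn: Mapping[str, Tuple[Set[str], Set[str]]],
    cancer_profiles: Mapping[str, pd.Series],
    normal_profile: pd.Series,
    top_n: int | str = 200,
) -> Dict[str, SubtypeSignature]:
    """Intersect the four gene sets defining each subtype's signature.

    Sets 1 and 2 are the TT and TN up sets. Set 3 is the ``top_n`` genes by
    cancer-compartment log2 FC of the subtype over the mean of the other
    subtypes' cancer compartments; set 4 the ``top_n`` by cancer-compartment
    FC over the normal mean profile. ``top_n="auto"`` uses
    max(|set1|, |set2|) per subtype.
    """
    subtypes = sorted(cancer_profiles)
    n_genes = len(normal_profile)
    out: Dict[str, SubtypeSignature] = {}
    for s in subtypes:
        tt, tn = tt_tn[s]
        n = max(len(tt), len(tn)) if top_n == "auto" else int(top_n)
        if n > n_genes:
            raise ValidationError(f"top_n={n} exceeds gene count {n_genes}")
        own = cancer_profiles[s]
        others = pd.concat([cancer_profiles[o] for o in subtypes if o != s], axis=1)
        fc_vs_rest = (own - others.mean(axis=1)).sort_values(ascending=False, kind="mergesort")
        fc_vs_normal = (own - normal_profile).sort_values(ascending=False, kind="mergesort")
        set3 = set(fc_vs_rest.index[:n])
        set4 = set(fc_vs_normal.index[:n])
        out[s] = SubtypeSignature(s, set(tt), set(tn), set3, set4)
    return out
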