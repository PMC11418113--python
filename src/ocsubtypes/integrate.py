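"""Merging multi-cohort expression, batch adjustment, variable-gene selection.

Batch adjustment is a direct per-gene per-cohort location/scale
standardization to the pooled gene mean and pooled SD. This is a documented
stand-in for ComBat: it removes cohort mean/scale structure, which is the
property downstream stages rely on, without the empirical-Bayes shrinkage.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, ValidationError


def merge_cohorts(matrices: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Merge cohorts on their common genes.

    Output genes are the intersection of the input gene sets in lexicographic
    order; samples are concatenated in input order. Each input must already
    carry a ``cohort`` annotation (or one is derived from its position).
    """
    if len(matrices) < 2:
        raise ValidationError("merge_cohorts requires at least two cohorts")
    common = set(matrices[0].genes)
    for m in matrices[1:]:
        common &= set(m.genes)
    if not common:
        raise ValidationError("no common genes across cohorts")
    genes = sorted(common)

    seen = set()
    for m in matrices:
        dup = seen & set(m.sample_ids)
        if dup:
            raise ValidationError(
                f"sample identifiers duplicated across cohorts: {sorted(dup)[:5]}"
            )
        seen |= set(m.sample_ids)

    values = pd.concat([m.values.loc[genes] for m in matrices], axis=1)
    annot: List[pd.DataFrame] = []
    for i, m in enumerate(matrices):
        a = m.samples.copy()
        if "cohort" not in a:
            a["cohort"] = f"cohort{i + 1}"
        annot.append(a)
    samples = pd.concat(annot, axis=0)
    return ExpressionMatrix(values, samples)


def adjust_batch(matrix: ExpressionMatrix, min_cohort_size: int = 3) -> ExpressionMatrix:
    """Standardize each cohort's per-gene location and scale to pooled values.

    For each gene, each cohort's values are centered at the cohort mean,
    rescaled from the within-cohort SD to the pooled within-cohort SD, and
    re-centered at the pooled gene mean. Genes with zero within-cohort
    variance skip the scale step for that cohort. Idempotent up to
    floating-point error.
    """
    if "cohort" not in matrix.samples:
        raise ValidationError("matrix has no cohort annotation")
    cohorts = matrix.samples["cohort"]
    uniq = cohorts.unique()
    if len(uniq) < 2:
        raise ValidationError("batch adjustment requires at least two cohorts")
    sizes = cohorts.value_counts()
    small = sizes[sizes < min_cohort_size]
    if len(small):
        raise ValidationError(
            f"cohorts with fewer than {min_cohort_size} samples: {list(small.index)}"
        )

    X = matrix.values.to_numpy(dtype=float, copy=True)
    pooled_mean = X.mean(axis=1)
    # pooled WITHIN-cohort SD: sqrt(sum_c (n_c - 1) s_c^2 / (N - C)).
    # Using this (not the overall SD) as the target scale makes the map a
    # fixed point: once every cohort has this SD, it is also the recomputed
    # pooled within-cohort SD, so a second pass changes nothing.
    ss_within = np.zeros(X.shape[0])
    for c in uniq:
        mask = (cohorts == c).to_numpy()
        block = X[:, mask]
        ss_within += block.var(axis=1, ddof=1) * (mask.sum() - 1)
    pooled_sd = np.sqrt(ss_within / (X.shape[1] - len(uniq)))
    for c in uniq:
        mask = (cohorts == c).to_numpy()
        block = X[:, mask]
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        scale = np.where((sd > 0) & (pooled_sd > 0), pooled_sd / np.where(sd > 0, sd, 1.0), 1.0)
        X[:, mask] = (block - mu[:, None]) * scale[:, None] + pooled_mean[:, None]
    out = pd.DataFrame(X, index=matrix.genes, columns=matrix.sample_ids)
    return ExpressionMatrix(out, matrix.samples.copy())


def select_variable_genes(matrix: ExpressionMatrix, n: int = 1500) -> List[str]:
    """Rank genes by median absolute deviation and return the top ``n``.

    MAD is the unscaled median of |x - median(x)| per gene (no 1.4826
    consistency constant: ranking is scale-invariant). Ties break
    lexicographically by gene name.
    """
    if n > matrix.n_genes:
        raise ValidationError(
            f"requested {n} genes but matrix has only {matrix.n_genes}"
        )
    X = matrix.values
    mad = (X.sub(X.median(axis=1), axis=0)).abs().median(axis=1)
    # stable sort over a lexicographically pre-sorted index implements the tie rule
    order = mad.loc[sorted(mad.index)].sort_values(ascending=False, kind="mergesort")
    return list(order.index[:n])
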