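"""Two-compartment expression deconvolution from bulk values and tumor purity.

Each bulk tumor sample is modelled as a purity-weighted mixture of a cancer
and a stromal compartment:

    e_i = p_i * e_cancer + (1 - p_i) * e_stroma

so for each gene within each subtype, ordinary least squares of expression on
purity gives e_stroma as the intercept and e_cancer as intercept + slope.
Estimates below zero on the (shifted nonnegative) scale are clipped to zero
and flagged; identifiability requires purity spread within the subtype.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, ValidationError


@dataclass
class CompartmentProfile:
    """Per-gene cancer/stroma mean expression estimates for one subtype."""

    subtype: str
    e_cancer: pd.Series
    e_stroma: pd.Series
    resid_sd: pd.Series
    clipped: pd.Series  # bool per gene: any estimate clipped at 0
    n_samples: int


def infer_compartments(
    matrix: ExpressionMatrix,
    assignments: pd.Series,
    purity: pd.Series | None = None,
    min_samples: int = 10,
    purity_sd_floor: float = 0.05,
    clip: bool = True,
) -> Dict[str, CompartmentProfile]:
    """Per-subtype per-gene OLS of expression on purity.

    ``purity`` defaults to the matrix's ``purity`` annotation. Each subtype
    needs at least ``min_samples`` samples and purity SD >=
    ``purity_sd_floor`` for a well-conditioned fit.
    """
    if purity is None:
        if "purity" not in matrix.samples:
            raise ValidationError("no purity annotation available")
        purity = matrix.samples["purity"]
    purity = purity.loc[assignments.index]
    if purity.isna().any():
        raise ValidationError("purity missing for some assigned samples")
    if ((purity <= 0) | (purity >= 1)).any():
        raise ValidationError("purity must lie strictly inside (0, 1)")

    out: Dict[str, CompartmentProfile] = {}
    for s in sorted(assignments.unique()):
        ids = assignments.index[assignments == s]
        if len(ids) < min_samples:
            raise ValidationError(
                f"subtype {s}: {len(ids)} samples < required {min_samples}"
            )
        p = purity.loc[ids].to_numpy()
        if p.std(ddof=0) < purity_sd_floor:
            raise ValidationError(
                f"subtype {s}: purity SD {p.std(ddof=0):.3f} below floor {purity_sd_floor}"
            )
        Y = matrix.values[ids].to_numpy()  # genes x n
        # closed-form simple OLS per gene against the shared regressor p
        p_mean = p.mean()
        p_c = p - p_mean
        denom = (p_c**2).sum()
        slope = (Y @ p_c) / denom
        intercept = Y.mean(axis=1) - slope * p_mean
        fitted = intercept[:, None] + slope[:, None] * p[None, :]
        resid = Y - fitted
        dof = max(len(ids) - 2, 1)
        resid_sd = np.sqrt((resid**2).sum(axis=1) / dof)
        e_stroma = intercept
        e_cancer = intercept + slope
        clipped = (e_cancer < 0) | (e_stroma < 0)
        if clip:
            e_cancer = np.maximum(e_cancer, 0.0)
            e_stroma = np.maximum(e_stroma, 0.0)
        out[s] = CompartmentProfile(
            subtype=s,
            e_cancer=pd.Series(e_cancer, index=matrix.genes),
            e_stroma=pd.Series(e_stroma, index=matrix.genes),
            resid_sd=pd.Series(resid_sd, index=matrix.genes),
            clipped=pd.Series(clipped, index=matrix.genes),
            n_samples=len(ids),
        )
    return out


def specificity_scores(
    profiles: Mapping[str, CompartmentProfile],
    genes: Sequence[str] | None = None,
    threshold: float = 1.0,
) -> pd.DataFrame:
    """One-vs-rest compartment specificity per gene, compartment and subtype.

    score(g, compartment, s) = compartment expression of g in subtype s minus
    the mean compartment expression of g over the other subtypes (log2
    difference). A gene is flagged specific when |score| > ``threshold``.
    """
    subtypes = sorted(profiles)
    if len(subtypes) < 2:
        raise ValidationError("specificity needs at least two subtypes")
    rows = []
    for comp in ("cancer", "stroma"):
        table = pd.concat(
            {s: getattr(profiles[s], f"e_{comp}") for s in subtypes}, axis=1
        )
        if genes is not None:
            present = [g for g in genes if g in table.index]
            table = table.loc[present]
        for s in subtypes:
            others = table[[o for o in subtypes if o != s]].mean(axis=1)
            score = table[s] - others
            rows.append(pd.DataFrame({
                "gene": table.index, "compartment": comp, "subtype": s,
                "score": score.to_numpy(),
                "specific": (score.abs() > threshold).to_numpy(),
            }))
    return pd.concat(rows, ignore_index=True)
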