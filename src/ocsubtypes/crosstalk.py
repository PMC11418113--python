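"""Relative-crosstalk (RC) scoring of ligand-receptor pairs.

The product of ligand and receptor expression estimates the activity of an
LR complex. With a cancer (C) and a stromal (S) compartment there are four
signalling directions; the RC score of a direction is that direction's
product as a share of the sum over all four, e.g. for cancer-to-cancer:

    S_CC = eL_C * eR_C / (eL_C*eR_C + eL_C*eR_S + eL_S*eR_C + eL_S*eR_S)

Scores therefore lie in [0, 1] and sum to 1 whenever at least one product is
positive. Compartment expressions are mapped from the clipped log2 scale to
linear scale (2^x - 1, floored at 0) before forming products, because
products of log intensities are not meaningful concentrations. The same math
applied to cell-type mean profiles scores crosstalk between cell populations.
"""

from __future__ import annotations

from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd

from .deconvolution import CompartmentProfile
from .matrix import ValidationError

DIRECTIONS = ("S_CC", "S_CS", "S_SC", "S_SS")

#: immune-checkpoint pairs reported on when present in the LR table
CHECKPOINT_PAIRS = (
    ("CD86", "CTLA4"), ("ICOSLG", "ICOS"), ("CD70", "CD27"),
    ("TNFSF9", "TNFRSF9"), ("PDCD1LG2", "PDCD1"), ("IFNG", "IFNGR2"),
)


def log2_to_linear(x) -> np.ndarray:
    """Map log2-scale expression to a nonnegative linear scale (2^x - 1)."""
    return np.maximum(np.exp2(np.asarray(x, dtype=float)) - 1.0, 0.0)


def _direction_scores(el_c, el_s, er_c, er_s):
    """Four direction scores from linear-scale expressions; None if all zero."""
    prods = np.array([el_c * er_c, el_c * er_s, el_s * er_c, el_s * er_s])
    total = prods.sum()
    if total <= 0:
        return None
    return prods / total


def rc_scores(
    profiles: Mapping[str, CompartmentProfile],
    lr_table: pd.DataFrame,
    linear_scale: bool = True,
) -> pd.DataFrame:
    """RC scores per LR pair per subtype.

    Pairs whose ligand or receptor is absent from the profiles are skipped
    (counted in the ``skipped`` attribute of the result); pairs with all four
    products zero are emitted with null scores.
    """
    subtypes = sorted(profiles)
    rows = []
    skipped = 0
    for _, pair in lr_table.iterrows():
        lig, rec = pair["ligand"], pair["receptor"]
        for s in subtypes:
            prof = profiles[s]
            if lig not in prof.e_cancer.index or rec not in prof.e_cancer.index:
                skipped += 1
                break
            el_c, el_s = prof.e_cancer[lig], prof.e_stroma[lig]
            er_c, er_s = prof.e_cancer[rec], prof.e_stroma[rec]
            if linear_scale:
                el_c, el_s, er_c, er_s = log2_to_linear([el_c, el_s, er_c, er_s])
            scores = _direction_scores(el_c, el_s, er_c, er_s)
            row = {"ligand": lig, "receptor": rec, "subtype": s,
                   "null": scores is None}
            for d, v in zip(DIRECTIONS, scores if scores is not None else [np.nan] * 4):
                row[d] = v
            rows.append(row)
    out = pd.DataFrame(
        rows, columns=["ligand", "receptor", "subtype", "null", *DIRECTIONS]
    )
    out.attrs["skipped"] = skipped
    return out


def comprehensive_rc(scores: pd.DataFrame) -> pd.DataFrame:
    """Mean direction scores across subtypes per LR pair.

    Only subtypes with defined (non-null) scores contribute; the count of
    contributing subtypes is reported as ``n_subtypes``.
    """
    defined = scores[~scores["null"]]
    if defined.empty:
        raise ValidationError("no pair has defined scores in any subtype")
    grouped = defined.groupby(["ligand", "receptor"], sort=True)
    out = grouped[list(DIRECTIONS)].mean()
    out["n_subtypes"] = grouped.size()
    return out.reset_index()


def top_pairs(
    scores: pd.DataFrame, direction: str, per_subtype_n: int = 5
) -> pd.DataFrame:
    """Top pairs per subtype for one direction; ties break by pair name."""
    if direction not in DIRECTIONS:
        raise ValidationError(f"direction must be one of {DIRECTIONS}")
    defined = scores[~scores["null"]].copy()
    defined = defined.sort_values(
        ["subtype", direction, "ligand", "receptor"],
        ascending=[True, False, True, True], kind="mergesort",
    )
    return (
        defined.groupby("subtype", sort=True)
        .head(per_subtype_n)
        .reset_index(drop=True)[["subtype", "ligand", "receptor", direction]]
    )


def celltype_rc(
    cell_matrix: pd.DataFrame,
    cell_types: pd.Series,
    lr_table: pd.DataFrame,
    type_a: str,
    type_b: str,
    min_cells: int = 10,
) -> pd.DataFrame:
    """RC scores between the mean profiles of two cell types.

    Type A plays the role of the cancer compartment and type B the stromal
    one, so ``S_CC`` is A-ligand to A-receptor signalling, ``S_CS`` A to B,
    etc. Cell expression is log-scale and converted with expm1-style mapping
    (2^x - 1) before averaging products.
    """
    cells_a = cell_types.index[cell_types == type_a]
    cells_b = cell_types.index[cell_types == type_b]
    if len(cells_a) < min_cells or len(cells_b) < min_cells:
        raise ValidationError(
            f"both cell types need >= {min_cells} cells "
            f"(got {len(cells_a)} {type_a!r}, {len(cells_b)} {type_b!r})"
        )
    mean_a = pd.Series(
        log2_to_linear(cell_matrix[cells_a]).mean(axis=1), index=cell_matrix.index
    )
    mean_b = pd.Series(
        log2_to_linear(cell_matrix[cells_b]).mean(axis=1), index=cell_matrix.index
    )
    rows = []
    for _, pair in lr_table.iterrows():
        lig, rec = pair["ligand"], pair["receptor"]
        if lig not in mean_a.index or rec not in mean_a.index:
            continue
        scores = _direction_scores(mean_a[lig], mean_b[lig], mean_a[rec], mean_b[rec])
        row = {"ligand": lig, "receptor": rec, "type_a": type_a, "type_b": type_b,
               "null": scores is None}
        for d, v in zip(DIRECTIONS, scores if scores is not None else [np.nan] * 4):
            row[d] = v
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["ligand", "receptor", "type_a", "type_b", "null", *DIRECTIONS]
    )
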