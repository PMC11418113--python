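"""Expression-matrix container shared by all pipeline stages.

Bulk and merged cohort expression is carried as a genes x samples table of
log2-scale values together with a per-sample annotation frame (cohort label,
tumor/normal flag, optional subtype, tumor purity, survival time/event).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass
class ExpressionMatrix:
    """Genes x samples log2-scale expression with sample annotations.

    Parameters
    ----------
    values:
        DataFrame with gene identifiers as the index and sample identifiers
        as columns. Values are on log2 scale.
    samples:
        DataFrame indexed by sample identifier (same order as ``values``
        columns). Recognized columns: ``cohort``, ``is_normal`` (bool),
        ``subtype``, ``purity`` (in the open interval (0, 1)), ``time``
        (> 0) and ``event`` (0/1).
    """

    values: pd.DataFrame
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.samples is None:
            self.samples = pd.DataFrame(index=self.values.columns)
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][:5].tolist()
            raise ValidationError(f"duplicate gene identifiers: {dup}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][:5].tolist()
            raise ValidationError(f"duplicate sample identifiers: {dup}")
        if not self.values.columns.equals(self.samples.index):
            if set(self.values.columns) != set(self.samples.index):
                raise ValidationError(
                    "sample annotation index does not match expression columns"
                )
            self.samples = self.samples.loc[self.values.columns]
        if "purity" in self.samples:
            p = self.samples["purity"].dropna()
            if ((p <= 0) | (p >= 1)).any():
                bad = p[(p <= 0) | (p >= 1)].index[:5].tolist()
                raise ValidationError(
                    f"purity must lie strictly inside (0, 1); offending samples: {bad}"
                )

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, ids) -> "ExpressionMatrix":
        ids = pd.Index(ids)
        return ExpressionMatrix(self.values[ids], self.samples.loc[ids])

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = pd.Index(genes)
        return ExpressionMatrix(self.values.loc[genes], self.samples)

    def tumor_samples(self) -> pd.Index:
        if "is_normal" not in self.samples:
            return self.sample_ids
        return self.samples.index[~self.samples["is_normal"].astype(bool)]

    def normal_samples(self) -> pd.Index:
        if "is_normal" not in self.samples:
            return pd.Index([])
        return self.samples.index[self.samples["is_normal"].astype(bool)]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.samples.copy())

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples, "
            f"annotations: {list(self.samples.columns)})"
        )


def check_positive(name: str, value) -> None:
    if value is None or not np.isfinite(value) or value <= 0:
        raise ValidationError(f"{name} must be positive, got {value!r}")
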