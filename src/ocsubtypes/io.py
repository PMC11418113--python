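"""Readers and writers for the pipeline's plain-text formats.

Dense expression is TSV with genes as rows (the microarray series-matrix
convention); sample/cell annotations are sidecar TSVs keyed by identifier;
gene sets use GMT; sparse single-cell matrices use the MTX triplet
(matrix.mtx, features.tsv, barcodes.tsv); LR pairs a two-column CSV; risk
models JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .matrix import ExpressionMatrix, ValidationError
from .survival import RiskModel, validate_survival

FLOAT_FMT = "%.10g"


def write_expression(matrix: ExpressionMatrix, prefix: str | Path) -> None:
    """Write values to <prefix>.tsv and annotations to <prefix>.samples.tsv."""
    prefix = Path(prefix)
    matrix.values.to_csv(
        prefix.with_suffix(".tsv"), sep="\t", float_format=FLOAT_FMT,
        index_label="gene",
    )
    matrix.samples.to_csv(
        prefix.with_suffix(".samples.tsv"), sep="\t", float_format=FLOAT_FMT,
        index_label="sample",
    )


def read_expression(prefix: str | Path) -> ExpressionMatrix:
    prefix = Path(prefix)
    values = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t", index_col="gene")
    sidecar = prefix.with_suffix(".samples.tsv")
    samples = None
    if sidecar.exists():
        samples = pd.read_csv(sidecar, sep="\t", index_col="sample")
        samples.index = samples.index.astype(str)
        for col in ("subtype", "cohort"):
            if col in samples:
                samples[col] = samples[col].fillna("")
    values.columns = values.columns.astype(str)
    return ExpressionMatrix(values, samples)


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path: str | Path,
              description: str = "") -> None:
    with open(path, "w") as fh:
        for name in gene_sets:
            genes = "\t".join(gene_sets[name])
            fh.write(f"{name}\t{description}\t{genes}\n")


def read_gmt(path: str | Path) -> Dict[str, List[str]]:
    out: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                if len(parts) == 2 or (len(parts) == 1 and not parts[0]):
                    if parts and parts[0]:
                        out[parts[0]] = []
                    continue
                raise ValidationError(f"malformed GMT line: {line!r}")
            out[parts[0]] = [g for g in parts[2:] if g]
    return out


def write_mtx(cell_matrix: pd.DataFrame, directory: str | Path) -> None:
    """Write a genes x cells matrix as an MTX triplet directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(directory / "matrix.mtx", sparse.csr_matrix(cell_matrix.to_numpy()))
    pd.Series(cell_matrix.index).to_csv(
        directory / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(cell_matrix.columns).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )


def read_mtx(directory: str | Path) -> pd.DataFrame:
    directory = Path(directory)
    m = spio.mmread(directory / "matrix.mtx").toarray()
    features = pd.read_csv(directory / "features.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)[0]
    return pd.DataFrame(m, index=features.astype(str), columns=barcodes.astype(str))


def write_lr_table(table: pd.DataFrame, path: str | Path) -> None:
    table[["ligand", "receptor"]].to_csv(path, index=False)


def read_lr_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if not {"ligand", "receptor"} <= set(table.columns):
        raise ValidationError("LR table needs 'ligand' and 'receptor' columns")
    return table


def write_survival(survival: pd.DataFrame, path: str | Path) -> None:
    validate_survival(survival).to_csv(
        path, sep="\t", float_format=FLOAT_FMT, index_label="sample"
    )


def read_survival(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col="sample")
    table.index = table.index.astype(str)
    return validate_survival(table)


def write_model(model: RiskModel, path: str | Path) -> None:
    payload = {
        "genes": model.genes,
        "coefficients": [float(c) for c in model.coefficients],
        "cutpoint": model.cutpoint,
        "provenance": model.provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_model(path: str | Path) -> RiskModel:
    payload = json.loads(Path(path).read_text())
    return RiskModel(
        genes=payload["genes"],
        coefficients=np.asarray(payload["coefficients"], dtype=float),
        cutpoint=payload["cutpoint"],
        provenance=payload.get("provenance", "fitted"),
    )
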