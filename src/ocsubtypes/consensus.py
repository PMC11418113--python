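"""Consensus NMF subtyping with cophenetic model selection.

For each candidate number of subtypes k, the expression matrix (shifted to a
nonnegative floor per gene) is factorized repeatedly from random starts; the
fraction of runs co-assigning two samples forms the consensus matrix. The
cophenetic coefficient of the 1 - consensus distance measures how ultrametric
(stable) the clustering is, and the k maximizing it is chosen. Final hard
assignments come from cutting the average-linkage dendrogram of that
distance, which makes labels independent of NMF component permutation.
Samples whose consensus silhouette width is not positive are filtered out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import silhouette_samples

from .matrix import ExpressionMatrix, ValidationError
from .simulate import subtype_labels


@dataclass
class ConsensusResult:
    """Per-k consensus matrices and diagnostics plus the final assignment."""

    sample_ids: pd.Index
    consensus: Dict[int, np.ndarray]
    cophenetic: Dict[int, float]
    assignments: Dict[int, pd.Series]  # labels C1..Ck, ordered by cluster size
    chosen_k: int = 0
    silhouette: pd.Series = field(default=None)  # type: ignore[assignment]
    retained: pd.Index = field(default=None)  # type: ignore[assignment]

    @property
    def final_assignments(self) -> pd.Series:
        return self.assignments[self.chosen_k]


def make_nonnegative(values: pd.DataFrame, method: str = "split") -> pd.DataFrame:
    """Map log-scale expression to a nonnegative matrix for NMF.

    ``"split"`` centers each gene and stacks the positive and negative parts
    as separate rows, removing baseline-expression dominance (the standard
    transform for NMF on signed data). ``"shift"`` subtracts each gene's
    minimum so its floor is zero.
    """
    if method == "shift":
        return values.sub(values.min(axis=1), axis=0)
    if method == "split":
        centered = values.sub(values.mean(axis=1), axis=0)
        pos = centered.clip(lower=0)
        neg = (-centered).clip(lower=0)
        pos.index = [f"{g}+" for g in centered.index]
        neg.index = [f"{g}-" for g in centered.index]
        return pd.concat([pos, neg])
    raise ValidationError(f"unknown nonnegativity method {method!r}")


def nmf_factorize(
    matrix: np.ndarray | pd.DataFrame, k: int, seed: int,
    max_iter: int = 500, tol: float = 1e-5,
) -> Tuple[np.ndarray, np.ndarray, bool]:
    """One NMF run (multiplicative updates) from a seeded random start.

    Returns ``(W, H, converged)`` with W genes x k and H k x samples. The
    sample cluster of column j is ``argmax(H[:, j])``.
    """
    X = np.asarray(matrix, dtype=float)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if X.min() < 0:
        raise ValidationError("matrix must be nonnegative (see make_nonnegative)")
    if not X.any():
        raise ValidationError("all-zero matrix cannot be factorized")
    model = NMF(
        n_components=k, init="random", solver="mu", beta_loss="frobenius",
        max_iter=max_iter, tol=tol, random_state=seed,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        W = model.fit_transform(X)
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    return W, model.components_, converged


def _connectivity(H: np.ndarray) -> np.ndarray:
    lab = H.argmax(axis=0)
    return (lab[:, None] == lab[None, :]).astype(float)


def _size_ordered_labels(clusters: np.ndarray, k: int) -> List[str]:
    """Map raw cluster ids to C1..Ck by decreasing cluster size (ties: id)."""
    ids, counts = np.unique(clusters, return_counts=True)
    order = ids[np.lexsort((ids, -counts))]
    mapping = {cid: f"C{i + 1}" for i, cid in enumerate(order)}
    return [mapping[c] for c in clusters]


def consensus_cluster(
    matrix: ExpressionMatrix | pd.DataFrame,
    k_range: Sequence[int] = range(2, 7),
    n_runs: int = 30,
    seed: int = 0,
    max_iter: int = 500,
    gene_subsample: float = 0.8,
    prep: str = "split",
) -> ConsensusResult:
    """Consensus NMF over a range of k.

    For each k, ``n_runs`` factorizations from distinct seeds produce a
    consensus matrix of co-assignment fractions; its cophenetic coefficient
    is the Pearson correlation between the 1 - consensus distances and the
    cophenetic distances of their average-linkage dendrogram. Hard
    assignments per k cut that dendrogram into k clusters, labelled C1..Ck
    by decreasing size (the labels themselves are arbitrary).

    Each run factorizes a random ``gene_subsample`` fraction of the genes
    (every sample participates in every run). Multiplicative-update NMF from
    random starts alone tends to reach the same partition in every run,
    leaving the consensus matrix 0/1 at several k and the cophenetic
    coefficient uninformative; gene resampling restores its discrimination.
    """
    if n_runs < 2:
        raise ValidationError("n_runs must be >= 2")
    if not 0 < gene_subsample <= 1:
        raise ValidationError("gene_subsample must lie in (0, 1]")
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    sample_ids = values.columns
    X = make_nonnegative(values, method=prep).to_numpy()
    n = X.shape[1]
    n_sub = max(2, int(round(gene_subsample * X.shape[0])))
    rng = np.random.default_rng(seed)

    consensus: Dict[int, np.ndarray] = {}
    coph: Dict[int, float] = {}
    assignments: Dict[int, pd.Series] = {}
    for k in k_range:
        C = np.zeros((n, n))
        for _ in range(n_runs):
            run_seed = int(rng.integers(0, 2**31 - 1))
            rows = rng.choice(X.shape[0], size=n_sub, replace=False)
            _, H, _ = nmf_factorize(X[rows], k, run_seed, max_iter=max_iter)
            C += _connectivity(H)
        C /= n_runs
        np.fill_diagonal(C, 1.0)
        C = (C + C.T) / 2
        consensus[k] = C

        dist = 1.0 - C
        np.fill_diagonal(dist, 0.0)
        condensed = squareform(dist, checks=False)
        Z = average(condensed)
        if condensed.std() == 0:
            coph[k] = 1.0  # perfectly flat distances are trivially ultrametric
        else:
            c, _ = cophenet(Z, condensed)
            coph[k] = float(c) if np.isfinite(c) else 1.0
        clusters = fcluster(Z, t=k, criterion="maxclust")
        assignments[k] = pd.Series(
            _size_ordered_labels(clusters, k), index=sample_ids
        )

    result = ConsensusResult(sample_ids, consensus, coph, assignments)
    result.chosen_k = select_k(result)
    result.silhouette = _consensus_silhouette(result)
    result.retained = silhouette_filter(result)
    return result


def select_k(result: ConsensusResult) -> int:
    """k with the maximal cophenetic coefficient; ties go to the smaller k."""
    best = max(sorted(result.cophenetic), key=lambda k: (result.cophenetic[k], -k))
    return int(best)


def _consensus_silhouette(result: ConsensusResult) -> pd.Series:
    k = result.chosen_k
    labels = result.assignments[k]
    dist = 1.0 - result.consensus[k]
    np.fill_diagonal(dist, 0.0)
    codes = pd.Categorical(labels).codes
    counts = np.bincount(codes)
    if len(np.unique(codes)) < 2:
        widths = np.zeros(len(labels))
    else:
        widths = silhouette_samples(np.clip(dist, 0, None), codes, metric="precomputed")
        widths = np.where(counts[codes] == 1, 0.0, widths)  # singleton width := 0
    return pd.Series(widths, index=result.sample_ids)


def silhouette_filter(result: ConsensusResult, threshold: float = 0.0) -> pd.Index:
    """Samples whose consensus silhouette width exceeds ``threshold``."""
    if result.chosen_k == 0:
        raise ValidationError("chosen k not set")
    sil = result.silhouette if result.silhouette is not None else _consensus_silhouette(result)
    return result.sample_ids[np.asarray(sil) > threshold]
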