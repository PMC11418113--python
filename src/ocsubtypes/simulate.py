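"""Synthetic multi-cohort bulk and single-cell data with planted structure.

The generators emulate the statistical shape of merged public ovarian-cancer
expression cohorts: several batches with additive offsets, four planted
expression subtypes, per-sample tumor purity mixing a subtype-specific cancer
profile with a shared stromal profile, right-censored survival whose hazard
depends on subtype, and a single-cell compartment of malignant epithelial
cells plus immune cells carrying subtype signatures and disease-stage labels.

Everything is simulated directly on log2 scale; there is no count layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .matrix import ExpressionMatrix, ValidationError

MALIGNANT = "malignant_epithelial"
TCELL = "t_cell"
STAGES = ("primary", "relapse", "metastasis")


@dataclass
class BulkSimConfig:
    """Parameters of the bulk multi-cohort generator.

    Shifts and standard deviations are in log2 units. ``hazard_multipliers``
    gives each subtype's hazard relative to a unit baseline (C1 worst when
    its multiplier is largest).
    """

    n_cohorts: int = 4
    samples_per_cohort: int = 50
    n_genes: int = 300
    n_subtypes: int = 4
    n_signature_genes_per_subtype: int = 40
    effect_size: float = 1.5
    batch_sd: float = 0.5
    noise_sd: float = 0.5
    purity_range: Tuple[float, float] = (0.4, 0.9)
    hazard_multipliers: Tuple[float, ...] = (3.0, 0.5, 1.0, 1.5)
    censoring_rate: float = 0.3
    n_normals: int = 20
    n_stromal_genes: int = 15
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    compartment_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_subtypes < 2:
            raise ValidationError("n_subtypes must be >= 2")
        lo, hi = self.purity_range
        if not (0 < lo < hi < 1):
            raise ValidationError("purity_range must satisfy 0 < lo < hi < 1")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be nonnegative")
        for name in ("n_cohorts", "samples_per_cohort", "n_genes",
                     "n_signature_genes_per_subtype"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_normals < 0:
            raise ValidationError("n_normals must be nonnegative")
        if len(self.hazard_multipliers) != self.n_subtypes:
            raise ValidationError(
                "hazard_multipliers must have one entry per subtype"
            )
        if not 0 <= self.censoring_rate < 1:
            raise ValidationError("censoring_rate must lie in [0, 1)")
        if self.n_subtypes * self.n_signature_genes_per_subtype + self.n_stromal_genes > self.n_genes:
            raise ValidationError(
                "n_genes too small for the requested signature and stromal gene blocks"
            )


@dataclass
class SCSimConfig:
    """Parameters of the single-cell generator."""

    n_cells_per_type_stage: int = 100
    cell_types: Tuple[str, ...] = (MALIGNANT, TCELL)
    stages: Tuple[str, ...] = STAGES
    subtype_mixture_by_stage: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {
            "primary": (0.2, 0.4, 0.3, 0.1),
            "relapse": (0.3, 0.3, 0.3, 0.1),
            "metastasis": (0.3, 0.1, 0.5, 0.1),
        }
    )
    signature_shift: float = 1.0
    noise_sd: float = 0.5
    baseline_mean: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells_per_type_stage <= 0:
            raise ValidationError("n_cells_per_type_stage must be positive")
        if MALIGNANT not in self.cell_types:
            raise ValidationError(f"cell_types must include {MALIGNANT!r}")
        for stage in self.stages:
            if stage not in self.subtype_mixture_by_stage:
                raise ValidationError(f"no subtype mixture given for stage {stage!r}")
            props = np.asarray(self.subtype_mixture_by_stage[stage], dtype=float)
            if props.min() < 0 or not np.isclose(props.sum(), 1.0):
                raise ValidationError(
                    f"subtype proportions for stage {stage!r} must be nonnegative and sum to 1"
                )


def subtype_labels(k: int) -> List[str]:
    return [f"C{i + 1}" for i in range(k)]


def _gene_names(n: int) -> List[str]:
    return [f"G{i:05d}" for i in range(n)]


def generate_bulk(config: BulkSimConfig) -> Tuple[ExpressionMatrix, dict]:
    """Simulate a merged multi-cohort bulk dataset with planted subtypes.

    Each tumor sample is a purity-weighted mixture of its subtype's cancer
    mean profile and a shared stromal profile, plus an additive per-cohort
    per-gene batch offset and Gaussian noise. Normal samples are drawn from
    a separate baseline profile without batch offsets.

    Returns the expression matrix (genes x samples) and a truth record with
    every planted parameter: profiles, signature gene lists, subtype labels,
    purities, and survival parameters.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    labels = subtype_labels(config.n_subtypes)

    # cancer and stroma share a baseline: most genes are expressed comparably
    # across compartments, with moderate gene-level divergence
    cancer_base = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    stroma = cancer_base + rng.normal(0.0, config.compartment_sd, config.n_genes)

    # disjoint signature blocks followed by a stroma-only block
    sig_genes: Dict[str, List[str]] = {}
    cancer_profiles = {}
    offset = 0
    for lab in labels:
        idx = slice(offset, offset + config.n_signature_genes_per_subtype)
        sig_genes[lab] = genes[idx]
        prof = cancer_base.copy()
        prof[idx] += config.effect_size
        cancer_profiles[lab] = prof
        offset += config.n_signature_genes_per_subtype
    stromal_genes = genes[offset:offset + config.n_stromal_genes]
    stroma[offset:offset + config.n_stromal_genes] += config.effect_size

    n_tumors = config.n_cohorts * config.samples_per_cohort
    cohorts = np.repeat(
        [f"cohort{i + 1}" for i in range(config.n_cohorts)], config.samples_per_cohort
    )
    true_subtype = rng.choice(labels, size=n_tumors)
    purity = rng.uniform(*config.purity_range, size=n_tumors)
    batch_offsets = {
        f"cohort{i + 1}": rng.normal(0.0, config.batch_sd, config.n_genes)
        for i in range(config.n_cohorts)
    }

    cols = {}
    sample_ids = [f"S{i:04d}" for i in range(n_tumors)]
    for j, sid in enumerate(sample_ids):
        mix = purity[j] * cancer_profiles[true_subtype[j]] + (1 - purity[j]) * stroma
        noise = rng.normal(0.0, config.noise_sd, config.n_genes) if config.noise_sd > 0 else 0.0
        cols[sid] = mix + batch_offsets[cohorts[j]] + noise

    # survival: exponential event times, uniform administrative censoring
    mult = dict(zip(labels, config.hazard_multipliers))
    hazards = np.array([mult[s] for s in true_subtype])
    event_time = rng.exponential(1.0 / hazards)
    time, event = _censor(event_time, config.censoring_rate, rng)

    # normal tissue carries no cancer compartment: its baseline is the
    # stromal profile perturbed at the gene level
    normal_ids = [f"N{i:04d}" for i in range(config.n_normals)]
    normal_profile = stroma + rng.normal(0.0, config.compartment_sd / 2,
                                         config.n_genes)
    for sid in normal_ids:
        noise = rng.normal(0.0, config.noise_sd, config.n_genes) if config.noise_sd > 0 else 0.0
        cols[sid] = normal_profile + noise

    values = pd.DataFrame(cols, index=genes)
    samples = pd.DataFrame(
        {
            "cohort": list(cohorts) + ["normal"] * config.n_normals,
            "is_normal": [False] * n_tumors + [True] * config.n_normals,
            "subtype": list(true_subtype) + [""] * config.n_normals,
            "purity": list(purity) + [np.nan] * config.n_normals,
            "time": list(time) + [np.nan] * config.n_normals,
            "event": list(event.astype(float)) + [np.nan] * config.n_normals,
        },
        index=sample_ids + normal_ids,
    )
    truth = {
        "config": config,
        "genes": genes,
        "subtypes": labels,
        "signature_genes": sig_genes,
        "stromal_genes": list(stromal_genes),
        "cancer_profiles": {k: v.copy() for k, v in cancer_profiles.items()},
        "stroma_profile": stroma.copy(),
        "normal_profile": normal_profile.copy(),
        "batch_offsets": batch_offsets,
        "true_subtype": pd.Series(true_subtype, index=sample_ids),
        "purity": pd.Series(purity, index=sample_ids),
        "hazard_multipliers": mult,
    }
    return ExpressionMatrix(values, samples), truth


def _censor(event_time: np.ndarray, rate: float, rng: np.random.Generator):
    """Uniform administrative censoring calibrated to the target rate.

    Censor times are Uniform(0, M); M is solved so that the expected censored
    fraction over the drawn event times equals ``rate``.
    """
    if rate <= 0:
        return event_time, np.ones(len(event_time), dtype=int)

    def frac(m):
        return np.minimum(event_time, m).sum() / (m * len(event_time)) - rate

    hi = event_time.max() * 10
    m = brentq(frac, event_time.min() * 1e-6, hi)
    censor = rng.uniform(0.0, m, size=len(event_time))
    event = (event_time <= censor).astype(int)
    time = np.minimum(event_time, censor)
    return time, event


def generate_singlecell(
    config: SCSimConfig, signatures: Mapping[str, Sequence[str]],
    gene_universe: Sequence[str] | None = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate single cells with latent subtype signatures and stage labels.

    Malignant epithelial cells draw a latent subtype per the stage-specific
    mixture and have that subtype's signature genes shifted up by
    ``signature_shift`` log2 units; all other cell types carry no shift.

    Returns ``(cell_matrix, cell_table)``: genes x cells log2 expression and
    a per-cell table with ``cell_type``, ``stage`` and ``latent_subtype``.
    """
    config.validate()
    if not signatures:
        raise ValidationError("signatures must be non-empty")
    if gene_universe is None:
        universe = sorted({g for gs in signatures.values() for g in gs})
        filler = [f"BG{i:05d}" for i in range(max(200, 4 * len(universe)))]
        gene_universe = universe + filler
    missing = sorted(
        {g for gs in signatures.values() for g in gs} - set(gene_universe)
    )
    if missing:
        raise ValidationError(f"signature genes absent from universe: {missing}")

    rng = np.random.default_rng(config.seed)
    genes = list(gene_universe)
    gene_pos = {g: i for i, g in enumerate(genes)}
    subtypes = list(signatures)
    for stage in config.stages:
        if len(config.subtype_mixture_by_stage[stage]) != len(subtypes):
            raise ValidationError(
                f"stage {stage!r} mixture has "
                f"{len(config.subtype_mixture_by_stage[stage])} proportions "
                f"but {len(subtypes)} signatures were given"
            )

    base = rng.normal(config.baseline_mean, 0.5, len(genes))
    cols, rows = {}, []
    c = 0
    for stage in config.stages:
        props = np.asarray(config.subtype_mixture_by_stage[stage], dtype=float)
        for ctype in config.cell_types:
            for _ in range(config.n_cells_per_type_stage):
                cid = f"cell{c:05d}"
                c += 1
                expr = base + rng.normal(0.0, config.noise_sd, len(genes))
                latent = ""
                if ctype == MALIGNANT:
                    latent = subtypes[rng.choice(len(subtypes), p=props)]
                    if config.signature_shift != 0:
                        idx = [gene_pos[g] for g in signatures[latent]]
                        expr[idx] += config.signature_shift
                cols[cid] = np.maximum(expr, 0.0)
                rows.append({"cell_type": ctype, "stage": stage,
                             "latent_subtype": latent})
    cell_matrix = pd.DataFrame(cols, index=genes)
    cell_table = pd.DataFrame(rows, index=cell_matrix.columns)
    return cell_matrix, cell_table


def generate_lr_table(
    n_pairs: int = 1400, gene_universe: Sequence[str] | None = None, seed: int = 0
) -> pd.DataFrame:
    """Draw distinct (ligand, receptor) gene pairs from a universe.

    A synthetic stand-in for curated ligand-receptor resources; the default
    size of 1400 pairs matches the curated table's scale.
    """
    if gene_universe is None:
        gene_universe = _gene_names(300)
    universe = list(dict.fromkeys(gene_universe))
    n_possible = len(universe) ** 2
    if n_pairs < 0 or n_pairs > n_possible:
        raise ValidationError(
            f"n_pairs={n_pairs} exceeds {n_possible} possible distinct pairs"
        )
    rng = np.random.default_rng(seed)
    seen = set()
    ligands, receptors = [], []
    while len(seen) < n_pairs:
        i, j = rng.integers(0, len(universe), size=2)
        if (i, j) not in seen:
            seen.add((i, j))
            ligands.append(universe[i])
            receptors.append(universe[j])
    return pd.DataFrame({"ligand": ligands, "receptor": receptors})
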