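"""End-to-end pipeline: simulate/load -> integrate -> subtype -> genes ->
deconvolve -> signatures -> crosstalk -> single-cell scoring -> risk model.

Every stage writes its artifact to the run directory, and a manifest records
parameters, stage seeds, and SHA-256 hashes of each artifact so a rerun with
the same inputs and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .consensus import consensus_cluster
from .crosstalk import comprehensive_rc, rc_scores
from .deconvolution import infer_compartments
from .degenes import f_scores, subtype_signatures, tt_tn_sets
from .integrate import adjust_batch, select_variable_genes
from .matrix import ExpressionMatrix, ValidationError
from .sc_scoring import assign_and_filter, score_cells, stage_proportions
from .simulate import (BulkSimConfig, SCSimConfig, generate_bulk,
                       generate_lr_table, generate_singlecell)
from .survival import fit_lasso_cox, logrank_test, oss_score, stratify

log = logging.getLogger("ocsubtypes")


@dataclass
class PipelineConfig:
    """Parameters of a full pipeline run (see docs/methods.md for defaults)."""

    out_dir: str = "run"
    seed: int = 0
    # simulation (used when no input expression is supplied)
    bulk: BulkSimConfig = field(default_factory=BulkSimConfig)
    sc: Optional[SCSimConfig] = field(default_factory=SCSimConfig)
    n_lr_pairs: int = 200
    # stage parameters
    n_variable_genes: int = 300
    k_min: int = 2
    k_max: int = 6
    n_runs: int = 10
    de_lfc: float = 1.0
    de_fdr: float = 0.05
    top_n: int | str = 200
    n_bins: int = 30
    per_bin: int = 100
    cv_folds: int = 5
    run_singlecell: bool = True
    run_risk: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        bulk = BulkSimConfig(**raw.pop("bulk", {}))
        sc = SCSimConfig(**raw.pop("sc", {})) if raw.get("run_singlecell", True) else None
        raw.pop("sc", None)
        return cls(bulk=bulk, sc=sc, **raw)


def _stage_seeds(seed: int, n: int = 16) -> list[int]:
    """Expand a global seed into independent stage seeds (all < 2^31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages, writing artifacts and a manifest to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    artifacts: Dict[str, Path] = {}

    current = {"name": "init"}

    def stage(name):
        current["name"] = name
        log.info("stage: %s", name)

    try:
        stage("simulate")
        bulk_cfg = BulkSimConfig(**{**config.bulk.__dict__, "seed": seeds[0]})
        matrix, truth = generate_bulk(bulk_cfg)
        pio.write_expression(matrix, out / "expression")
        artifacts["expression"] = out / "expression.tsv"
        artifacts["samples"] = out / "expression.samples.tsv"
        lr_table = generate_lr_table(
            config.n_lr_pairs, gene_universe=list(matrix.genes), seed=seeds[1]
        )
        pio.write_lr_table(lr_table, out / "lr_pairs.csv")
        artifacts["lr_pairs"] = out / "lr_pairs.csv"

        stage("integrate")
        tumors = matrix.subset_samples(matrix.tumor_samples())
        adjusted = adjust_batch(tumors)
        variable = select_variable_genes(adjusted, n=min(config.n_variable_genes,
                                                         adjusted.n_genes))
        sub = adjusted.subset_genes(variable)

        stage("subtype")
        result = consensus_cluster(
            sub, k_range=range(config.k_min, config.k_max + 1),
            n_runs=config.n_runs, seed=seeds[2],
        )
        retained = result.retained
        assignments = result.final_assignments.loc[retained]
        pd.DataFrame({
            "subtype": result.final_assignments,
            "silhouette": result.silhouette,
            "retained": result.sample_ids.isin(retained),
        }).to_csv(out / "assignments.tsv", sep="\t", index_label="sample",
                  float_format=pio.FLOAT_FMT)
        artifacts["assignments"] = out / "assignments.tsv"
        pd.Series(result.cophenetic, name="cophenetic").to_csv(
            out / "cophenetic.tsv", sep="\t", index_label="k",
            float_format=pio.FLOAT_FMT)
        artifacts["cophenetic"] = out / "cophenetic.tsv"

        stage("genes")
        retained_matrix = adjusted.subset_samples(assignments.index)
        normals = matrix.subset_samples(matrix.normal_samples())
        combined = ExpressionMatrix(
            pd.concat([retained_matrix.values, normals.values], axis=1),
            pd.concat([retained_matrix.samples, normals.samples]),
        )
        tt_tn = tt_tn_sets(combined, assignments, list(normals.sample_ids),
                           lfc=config.de_lfc, fdr=config.de_fdr)
        fs = f_scores(retained_matrix, assignments)
        fs.to_csv(out / "f_scores.tsv", sep="\t", index_label="gene",
                  float_format=pio.FLOAT_FMT)
        artifacts["f_scores"] = out / "f_scores.tsv"

        stage("deconvolve")
        if "purity" not in matrix.samples or matrix.samples.loc[
                assignments.index, "purity"].isna().any():
            raise ValidationError("deconvolution requires a purity annotation")
        profiles = infer_compartments(retained_matrix, assignments,
                                      min_samples=5)
        prof_rows = []
        for s, prof in profiles.items():
            prof_rows.append(pd.DataFrame({
                "gene": prof.e_cancer.index, "subtype": s,
                "e_cancer": prof.e_cancer.to_numpy(),
                "e_stroma": prof.e_stroma.to_numpy(),
                "resid_sd": prof.resid_sd.to_numpy(),
                "clipped": prof.clipped.to_numpy(),
            }))
        pd.concat(prof_rows).to_csv(out / "compartments.tsv", sep="\t",
                                    index=False, float_format=pio.FLOAT_FMT)
        artifacts["compartments"] = out / "compartments.tsv"

        stage("signatures")
        normal_profile = normals.values.mean(axis=1)
        sigs = subtype_signatures(
            tt_tn, {s: p.e_cancer for s, p in profiles.items()},
            normal_profile, top_n=config.top_n,
        )
        sig_sets = {s: sig.genes for s, sig in sigs.items()}
        pio.write_gmt(sig_sets, out / "signatures.gmt")
        artifacts["signatures"] = out / "signatures.gmt"

        stage("crosstalk")
        scores = rc_scores(profiles, lr_table)
        scores.to_csv(out / "rc_scores.tsv", sep="\t", index=False,
                      float_format=pio.FLOAT_FMT)
        artifacts["rc_scores"] = out / "rc_scores.tsv"
        comprehensive_rc(scores).to_csv(
            out / "rc_comprehensive.tsv", sep="\t", index=False,
            float_format=pio.FLOAT_FMT)
        artifacts["rc_comprehensive"] = out / "rc_comprehensive.tsv"

        if config.run_singlecell and config.sc is not None:
            stage("sc")
            # fall back to planted signatures when the fitted ones are sparse
            sc_sigs = {
                s: (sig_sets[s] if len(sig_sets[s]) >= 3
                    else sorted(truth["signature_genes"][s]))
                for s in sig_sets
            }
            sc_cfg = SCSimConfig(**{**config.sc.__dict__, "seed": seeds[3]})
            # the configured stage mixtures assume a particular subtype
            # count; if consensus chose a different k, fall back to uniform
            if any(len(sc_cfg.subtype_mixture_by_stage[st]) != len(sc_sigs)
                   for st in sc_cfg.stages):
                uniform = tuple(1.0 / len(sc_sigs) for _ in sc_sigs)
                sc_cfg = SCSimConfig(**{
                    **sc_cfg.__dict__,
                    "subtype_mixture_by_stage": {st: uniform
                                                 for st in sc_cfg.stages},
                })
            cell_matrix, cell_table = generate_singlecell(
                sc_cfg, sc_sigs, gene_universe=list(matrix.genes))
            sc_scores = score_cells(
                cell_matrix, sc_sigs, n_bins=config.n_bins,
                per_bin=config.per_bin, seed=seeds[4])
            malignant = cell_table.index[cell_table["cell_type"]
                                         == "malignant_epithelial"]
            table = assign_and_filter(sc_scores.loc[malignant])
            table.to_csv(out / "cell_scores.tsv", sep="\t",
                         index_label="cell", float_format=pio.FLOAT_FMT)
            artifacts["cell_scores"] = out / "cell_scores.tsv"
            props = stage_proportions(table, cell_table["stage"])
            props.to_csv(out / "stage_proportions.tsv", sep="\t",
                         float_format=pio.FLOAT_FMT)
            artifacts["stage_proportions"] = out / "stage_proportions.tsv"

        if config.run_risk:
            stage("risk")
            surv = matrix.samples.loc[assignments.index, ["time", "event"]]
            # candidates: union of the extreme-prognosis subtypes' planted or
            # fitted signatures, padded with top-F genes
            cand = sorted(set().union(*(sig_sets[s] for s in sig_sets)))
            if len(cand) < 5:
                cand = sorted(fs.sort_values(ascending=False).index[:50])
            try:
                model = fit_lasso_cox(retained_matrix, surv, cand,
                                      cv_folds=config.cv_folds, seed=seeds[5])
            except ValidationError:
                # 1-SE penalty selected the null model; fall back to the
                # minimum-deviance penalty
                model = fit_lasso_cox(retained_matrix, surv, cand,
                                      cv_folds=config.cv_folds, seed=seeds[5],
                                      rule="min")
            pio.write_model(model, out / "risk_model.json")
            artifacts["risk_model"] = out / "risk_model.json"
            scores_oss = oss_score(model, retained_matrix)
            groups = stratify(scores_oss, model.cutpoint)
            if groups.nunique() == 2:
                chi2, p = logrank_test(groups, surv)
            else:
                chi2, p = float("nan"), float("nan")
            pd.DataFrame({"oss": scores_oss, "group": groups}).to_csv(
                out / "risk_scores.tsv", sep="\t", index_label="sample",
                float_format=pio.FLOAT_FMT)
            artifacts["risk_scores"] = out / "risk_scores.tsv"
            (out / "logrank.json").write_text(
                json.dumps({"chi2": chi2, "p": p}, indent=2) + "\n")
            artifacts["logrank"] = out / "logrank.json"
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage {current['name']!r} "
            f"(partial outputs retained in {out}): {exc}"
        ) from exc

    manifest = {
        "seed": config.seed,
        "stage_seeds": seeds[:6],
        # out_dir is excluded so manifests are byte-identical across reruns
        # of the same seed into different directories
        "parameters": {
            k: v for k, v in config.__dict__.items()
            if k not in ("bulk", "sc", "out_dir")
        },
        "bulk_config": {k: list(v) if isinstance(v, tuple) else v
                        for k, v in config.bulk.__dict__.items()},
        "artifacts": {k: _sha256(v) for k, v in artifacts.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return out
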