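"""Orchestration: config, the full cGWAS pipeline and the k-sweep experiment.

Stage order: QC -> PCA sample exclusion -> feature building -> DEC ->
pooled scan -> per-cluster cGWAS -> clumping/annotation -> reports. Every
stage writes TSV so a run can be resumed or inspected stage by stage, and a
manifest records the seeds and thresholds that produced each file. One
global seed fans out to per-stage seeds through a fixed SeedSequence
derivation, so reruns are bit-reproducible for all TSV outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import run_cgwas, run_scan
from .dec import DECHyperparams, fit_dec
from .features import ID_COLUMN, build_feature_matrix
from .genotypes import read_genotypes
from .postprocess import read_gene_model, render_reports
from .qc import apply_variant_filters, pca_outliers


@dataclass
class RunConfig:
    genotypes: str
    phenotypes: str
    outdir: str
    gene_model: str = None
    genotype_format: str = "vcf"
    run_name: str = None  # default: timestamped
    # QC
    maf_min: float = 0.01
    callrate_min: float = 0.95
    hwe_p_min: float = 1e-6
    pca_sd_threshold: float = 6.0
    # clustering
    dec: DECHyperparams = field(default_factory=DECHyperparams)
    standardize_features: bool = True
    # scans
    min_cases: int = 10
    alpha: float = 5e-8
    # clumping
    clump_r2: float = 0.1
    clump_window_kb: float = 250.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        dec = DECHyperparams(**raw.pop("dec", {}))
        return cls(dec=dec, **raw)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        order = ["qc", "features", "dec", "scan", "report"]
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(len(order))
        return int(children[order.index(stage)].generate_state(1)[0] % (2**31))


def _split_cases_controls(gm, pheno):
    """Cases = samples present in the phenotype table; controls = the rest."""
    pheno_ids = set(pheno[ID_COLUMN])
    case_ids = [s for s in gm.sample_ids if s in pheno_ids]
    control_ids = [s for s in gm.sample_ids if s not in pheno_ids]
    if not case_ids or not control_ids:
        raise ValueError(
            "need both cases (samples in the phenotype table) and controls "
            "(genotyped samples absent from it)"
        )
    return case_ids, control_ids


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the run directory."""
    run_name = config.run_name or time.strftime("run_%Y%m%d_%H%M%S")
    rundir = Path(config.outdir) / run_name
    rundir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "cgwas_version": __version__,
        "seed": config.seed,
        "config": {
            k: (asdict(v) if isinstance(v, DECHyperparams) else v)
            for k, v in asdict(config).items()
        },
        "stages": {},
    }

    def _stage(name):
        manifest["stages"][name] = {"status": "running"}
        return name

    try:
        stage = _stage("qc")
        gm = read_genotypes(config.genotypes, format=config.genotype_format)
        gm, report = apply_variant_filters(
            gm, config.maf_min, config.callrate_min, config.hwe_p_min
        )
        report.to_frame().to_csv(rundir / "filter_report.tsv", sep="\t", index=False)
        excluded = pca_outliers(gm, sd_threshold=config.pca_sd_threshold)
        (rundir / "excluded_samples.txt").write_text("\n".join(excluded) + ("\n" if excluded else ""))
        if excluded:
            keep = [s for s in gm.sample_ids if s not in set(excluded)]
            gm = gm.subset_samples(keep)
        manifest["stages"]["qc"] = {
            "n_variants_retained": gm.n_variants,
            "n_samples_excluded": len(excluded),
        }

        stage = _stage("features")
        pheno = pd.read_csv(config.phenotypes)
        pheno = pheno[pheno[ID_COLUMN].isin(set(gm.sample_ids))].reset_index(drop=True)
        case_ids, control_ids = _split_cases_controls(gm, pheno)
        features = build_feature_matrix(pheno, standardize=config.standardize_features)
        features.to_frame().to_csv(rundir / "features.tsv", sep="\t", index=False)
        manifest["stages"]["features"] = {
            "n_cases": len(case_ids),
            "n_controls": len(control_ids),
            "n_features": features.n_features,
        }

        stage = _stage("dec")
        model, assignment = fit_dec(features, config.dec)
        pd.DataFrame(
            {
                ID_COLUMN: assignment.sample_ids,
                "hard_label": assignment.labels,
                "max_q": assignment.Q.max(axis=1),
            }
        ).to_csv(rundir / "clusters.tsv", sep="\t", index=False)
        manifest["stages"]["dec"] = {
            "k": config.dec.k,
            "n_nonempty_clusters": assignment.n_nonempty,
            "seed": config.dec.seed,
        }

        stage = _stage("scan")
        pooled = run_scan(gm, case_ids, control_ids, label="pooled")
        pooled.to_tsv(rundir / "scan_pooled.tsv")
        cg = run_cgwas(
            gm, assignment, control_ids, min_cases=config.min_cases, alpha=config.alpha
        )
        for s in cg.scans:
            s.to_tsv(rundir / f"scan_{s.label}.tsv")
        lam = pd.DataFrame(
            [("pooled", pooled.lambda_, pooled.n_case, pooled.n_control)]
            + [(s.label, s.lambda_, s.n_case, s.n_control) for s in cg.scans],
            columns=["scan", "lambda", "n_case", "n_control"],
        )
        lam.to_csv(rundir / "lambdas.tsv", sep="\t", index=False)
        manifest["stages"]["scan"] = {
            "pooled_lambda": pooled.lambda_,
            "mean_cluster_lambda": cg.mean_lambda,
            "n_eligible_clusters": len(cg.scans),
            "n_significant_records": int(len(cg.significant)),
        }

        stage = _stage("report")
        gene_model = read_gene_model(config.gene_model) if config.gene_model else None
        render_reports(
            cg,
            pooled,
            rundir,
            gm=gm,
            gene_model=gene_model,
            phenotypes=pheno,
            assignment=assignment,
            clump_kwargs={
                "r2_threshold": config.clump_r2,
                "window_kb": config.clump_window_kb,
            },
        )
        manifest["stages"]["report"] = {"done": True}
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    with open(rundir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return rundir


def k_sweep(
    features,
    gm,
    control_ids,
    k_values,
    hyper_base: DECHyperparams,
    min_cases: int = 10,
    alpha: float = 5e-8,
    clump_r2: float = 0.1,
    clump_window_kb: float = 250.0,
) -> pd.DataFrame:
    """cGWAS over a grid of k on one cohort and seed.

    Returns one row per k: non-empty cluster count, mean lambda, the count
    of clumped significant loci, and a flag for mean lambda >= 1.05 (the
    validity rule: such a k is considered unsafely inflated).
    """
    from dataclasses import replace

    from .postprocess import clump

    if not len(k_values):
        raise ValueError("k_values must be non-empty")
    rows = []
    for k in k_values:
        hyper = replace(hyper_base, k=int(k))
        _model, assignment = fit_dec(features, hyper)
        cg = run_cgwas(gm, assignment, control_ids, min_cases=min_cases, alpha=alpha)
        n_loci = sum(
            len(clump(s, gm, p1=alpha, r2_threshold=clump_r2, window_kb=clump_window_kb))
            for s in cg.scans
        )
        rows.append(
            {
                "k": int(k),
                "n_nonempty_clusters": assignment.n_nonempty,
                "mean_lambda": cg.mean_lambda,
                "n_significant_loci": n_loci,
                "lambda_inflated": bool(cg.mean_lambda >= 1.05)
                if np.isfinite(cg.mean_lambda)
                else False,
            }
        )
    return pd.DataFrame(rows)


def experiment_k_sweep(config: RunConfig, k_values) -> pd.DataFrame:
    """File-based wrapper around :func:`k_sweep` using a RunConfig."""
    gm = read_genotypes(config.genotypes, format=config.genotype_format)
    gm, _report = apply_variant_filters(
        gm, config.maf_min, config.callrate_min, config.hwe_p_min
    )
    pheno = pd.read_csv(config.phenotypes)
    pheno = pheno[pheno[ID_COLUMN].isin(set(gm.sample_ids))].reset_index(drop=True)
    case_ids, control_ids = _split_cases_controls(gm, pheno)
    features = build_feature_matrix(pheno, standardize=config.standardize_features)
    return k_sweep(
        features,
        gm,
        control_ids,
        k_values,
        config.dec,
        min_cases=config.min_cases,
        alpha=config.alpha,
        clump_r2=config.clump_r2,
        clump_window_kb=config.clump_window_kb,
    )
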