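"""End-to-end orchestration of the association workflow.

Stages: normalize (modified RPKM or geometric-mean-only) -> prevalence
filter -> Taylor-law Tweedie fit -> genotype QC (missing, MAF, HWE, LD)
-> additive/dominance coding -> ancestry PCs -> mixed-model
residualization of both views -> cross-validated sparse CCA with
deflation -> optional enrichment.  Per-stage feature/locus counts are
logged, mirroring how cohort studies report survivors of each filter.

The permutation check refits the selection on abundance rows shuffled
across samples; low overlap with the unpermuted selection indicates the
discovered sets are not artifacts of the selection procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import abundance as ab
from . import genotype as gt
from .residualize import gaussian_lmm_residuals, tweedie_glmm_residuals
from .scca import PenaltyGrid, SccaModel, run_scca, selection_overlap
from .simulate import SyntheticCohort

logger = logging.getLogger("microscca")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "permutation_overlap", "recovery_metrics"]


@dataclass
class PipelineConfig:
    """Workflow settings; defaults mirror the emulated study protocol."""

    normalization: str = "auto"  # auto | modified_rpkm | geometric_mean_only
    min_prevalence: float = 0.10
    min_maf: float = 0.10
    hwe_alpha: float = 0.001
    ld_window: int = 50
    ld_step: int = 10
    ld_r2: float = 0.8
    n_pcs: int = 10
    residual_type: str = "pearson"
    tweedie_power: float | None = None  # None: estimate from the table
    n_components: int = 2
    mixing: float = 0.5
    cv_folds: int = 5
    ridge: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.normalization not in ("auto", "modified_rpkm", "geometric_mean_only"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclass
class PipelineResult:
    model: SccaModel
    tweedie_fit: object
    normalized: ab.FeatureTable
    filtered: ab.FeatureTable
    genotypes_qc: gt.GenotypeMatrix
    coded: gt.CodedGenotypeMatrix
    x_residuals: pd.DataFrame
    y_residuals: pd.DataFrame
    groups: pd.Series
    stage_log: dict = field(default_factory=dict)
    config: PipelineConfig | None = None

    def selected(self, side: str = "features") -> set:
        attr = "selected_features" if side == "features" else "selected_snps"
        out: set = set()
        for comp in self.model.components:
            out |= set(getattr(comp, attr))
        return out


def run_pipeline(
    counts: ab.FeatureTable,
    genotypes: gt.GenotypeMatrix,
    covariates: pd.DataFrame,
    config: PipelineConfig | None = None,
    grid: PenaltyGrid | None = None,
) -> PipelineResult:
    """Run every stage on in-memory tables and return all artifacts."""
    cfg = config if config is not None else PipelineConfig()
    log: dict = {}

    # --- abundance side ---------------------------------------------------
    mode = cfg.normalization
    if mode == "auto":
        mode = "modified_rpkm" if counts.lengths is not None else "geometric_mean_only"
    norm = ab.modified_rpkm(counts) if mode == "modified_rpkm" else ab.normalize_geometric_mean(counts)
    filtered = ab.prevalence_filter(norm, cfg.min_prevalence)
    log["features_in"] = counts.n_features
    log["features_after_prevalence"] = filtered.n_features
    logger.info("prevalence filter: %d -> %d features", counts.n_features, filtered.n_features)

    fit = ab.estimate_taylor_power(filtered)
    power = cfg.tweedie_power if cfg.tweedie_power is not None else fit.p
    if not (1.0 < power < 2.0):
        clipped = float(np.clip(power, 1.01, 1.99))
        logger.warning("Taylor power %.3f outside (1,2); clipped to %.2f", power, clipped)
        power = clipped
    log["tweedie_p"] = power
    log["tweedie_phi"] = fit.phi

    # --- genotype side ----------------------------------------------------
    g = gt.filter_missing(genotypes)
    log["loci_after_missing"] = g.n_loci
    g = gt.filter_maf(g, cfg.min_maf)
    log["loci_after_maf"] = g.n_loci
    g = gt.filter_hwe(g, cfg.hwe_alpha)
    log["loci_after_hwe"] = g.n_loci
    g = gt.ld_prune(g, cfg.ld_window, cfg.ld_step, cfg.ld_r2)
    log["loci_after_ld"] = g.n_loci
    logger.info(
        "genotype QC: %d -> %d loci", genotypes.n_loci, g.n_loci
    )
    coded = gt.code_additive_dominance(g)
    k = min(cfg.n_pcs, g.n_loci)
    pcs = gt.ancestry_pcs(g, k=k, family_ids=covariates["family_id"])
    cov = covariates.join(pcs)

    # --- residualization --------------------------------------------------
    yres = tweedie_glmm_residuals(
        filtered, cov, power, residual_type=cfg.residual_type
    )
    log["features_excluded"] = yres.excluded
    xres = gaussian_lmm_residuals(coded, cov)
    groups = xres.groups

    # --- sparse CCA -------------------------------------------------------
    model = run_scca(
        xres.values,
        yres.values,
        groups.to_numpy(),
        grid=grid,
        n_components=cfg.n_components,
        folds=cfg.cv_folds,
        seed=cfg.seed,
        mixing=cfg.mixing,
        ridge=cfg.ridge,
    )
    log["components"] = len(model.components)
    return PipelineResult(
        model=model,
        tweedie_fit=fit,
        normalized=norm,
        filtered=filtered,
        genotypes_qc=g,
        coded=coded,
        x_residuals=xres.values,
        y_residuals=yres.values,
        groups=groups,
        stage_log=log,
        config=cfg,
    )


def recovery_metrics(result: PipelineResult, truth: dict) -> dict:
    """Planted-set recall and false-selection rate of a pipeline run.

    Feature side: recall = fraction of planted features in the selected
    union; false-selection rate (FSR) = fraction of selections that are
    not planted.

    Variant side: scored at the LD-block level.  A planted variant may
    itself be removed by QC (HWE rejection, LD pruning) while its
    block-mates carry most of its signal, so a planted group counts as
    recovered if any selected locus lies in its LD block, and a
    selection is false only if it lies outside every planted block --
    the tag-variant convention of GWAS simulation studies.  Strict
    locus-identity recall is reported alongside.
    """
    out = {}
    planted_feats = set(truth["planted_features"])
    sel_feats = result.selected("features")
    out["features_recall"] = (
        len(sel_feats & planted_feats) / len(planted_feats) if planted_feats else float("nan")
    )
    out["features_false_selection_rate"] = (
        len(sel_feats - planted_feats) / len(sel_feats) if sel_feats else 0.0
    )
    out["features_n_selected"] = len(sel_feats)

    planted_loci = set(truth["planted_loci"])
    sel_snps = result.selected("snps")
    block_members = [set(b) for b in truth.get("planted_block_members", [])]
    if not block_members:
        block_members = [{p} for p in planted_loci]
    in_planted_block = set().union(*block_members) if block_members else set()
    recovered = sum(1 for b in block_members if b & sel_snps)
    out["snps_recall"] = recovered / len(block_members) if block_members else float("nan")
    out["snps_strict_recall"] = (
        len(sel_snps & planted_loci) / len(planted_loci) if planted_loci else float("nan")
    )
    out["snps_false_selection_rate"] = (
        len(sel_snps - in_planted_block) / len(sel_snps) if sel_snps else 0.0
    )
    out["snps_n_selected"] = len(sel_snps)
    return out


def permutation_overlap(
    result: PipelineResult,
    n_permutations: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Refit selection on sample-permuted abundance residuals.

    Each permutation shuffles the rows of the abundance residual matrix
    (breaking the X-Y pairing while preserving both marginals), reruns
    the sparse-CCA selection with the same settings, and reports the
    fraction of the original selections recovered, per side.
    """
    rng = np.random.default_rng(seed)
    cfg = result.config or PipelineConfig()
    orig_snps = result.selected("snps")
    orig_feats = result.selected("features")
    rows = []
    for b in range(n_permutations):
        perm = rng.permutation(result.y_residuals.shape[0])
        yperm = pd.DataFrame(
            result.y_residuals.to_numpy()[perm],
            index=result.y_residuals.index,
            columns=result.y_residuals.columns,
        )
        model = run_scca(
            result.x_residuals,
            yperm,
            result.groups.to_numpy(),
            n_components=cfg.n_components,
            folds=cfg.cv_folds,
            seed=cfg.seed,
            mixing=cfg.mixing,
            ridge=cfg.ridge,
        )
        snps, feats = set(), set()
        for comp in model.components:
            snps |= set(comp.selected_snps)
            feats |= set(comp.selected_features)
        rows.append(
            {
                "permutation": b,
                "snp_overlap": selection_overlap(orig_snps, snps),
                "feature_overlap": selection_overlap(orig_feats, feats),
                "n_snps_permuted": len(snps),
                "n_features_permuted": len(feats),
            }
        )
    return pd.DataFrame(rows)
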