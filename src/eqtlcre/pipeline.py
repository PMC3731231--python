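"""End-to-end orchestration: simulate -> preprocess -> map -> FDR ->
overlap/enrichment -> replication -> bivariate -> classify -> GWAS transfer.

Every stage is deterministic given the configuration seed; stage outputs are
written as TSV/JSON so two runs with the same config produce byte-identical
files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .bayes import PriorGrid, batch_univariate_log10bf
from .bivariate import classify_bivariate_batch
from .classify import (ablate_cre_features, annotate_gwas, assemble_features,
                       cross_validate_rf)
from .config import PipelineConfig
from .overlap import (annotate_snps, background_snps, build_snp_pairs,
                      intervening_flags, snp_overlaps)
from .preprocess import ExpressionMatrix, normalize_expression, remove_pcs
from .replication import call_replication, fit_enrichment
from .simulate import StudySet, simulate_study_set
from .tiers import hotspot_intervals, ld_blocks, permutation_fdr

__all__ = ["PipelineResult", "run_pipeline", "residualize_study",
           "target_association_table", "significant_records"]


@dataclass
class PipelineResult:
    config: PipelineConfig
    study: StudySet
    residuals: dict            # study id -> residual trait DataFrame
    records_all: pd.DataFrame  # unthresholded discovery records
    fdr_table: pd.DataFrame
    cutoffs: dict              # tier -> BF cutoff (or None)
    records: pd.DataFrame      # significant discovery records
    replication: pd.DataFrame
    enrichment: dict           # model id -> coefficient table
    bivariate: pd.DataFrame
    bivariate_summary: pd.DataFrame
    classifier: dict           # task -> report summary
    gwas: dict


def residualize_study(intensities: pd.DataFrame, knn_k: int,
                      pve_delta: float) -> tuple[pd.DataFrame, dict]:
    """Intensities -> residual standard-normal traits (the association input)."""
    raw = ExpressionMatrix(intensities, stage="raw")
    norm = normalize_expression(raw, knn_k=knn_k)
    resid, report = remove_pcs(norm, pve_delta=pve_delta)
    return resid.values, report.to_dict()


def target_association_table(traits: pd.DataFrame, genotypes_by_chrom: dict,
                             pairs: pd.DataFrame,
                             prior: PriorGrid) -> pd.DataFrame:
    """Univariate log10 BF + MAF in a target study for given (gene, snp) pairs."""
    rows = []
    for (gene, chrom), grp in pairs.groupby(["GENE", "CHR"]):
        if gene not in traits.columns:
            continue
        gt = genotypes_by_chrom[chrom]
        idx = [gt.snp_ids.index(s) for s in grp["RSID"]]
        G = gt.dosages[:, idx]
        poly = G.std(axis=0) > 0
        bf = np.full(len(idx), -np.inf)
        if poly.any():
            bf[poly] = batch_univariate_log10bf(
                traits[gene].to_numpy(), G[:, poly], prior)
        for snp, b, j in zip(grp["RSID"], bf, idx):
            rows.append((gene, snp, float(b), float(gt.maf[j])))
    return pd.DataFrame(rows, columns=["gene_id", "snp_id", "log10bf", "maf"])


def significant_records(records: pd.DataFrame, cutoffs: dict) -> pd.DataFrame:
    """Keep consecutive significant tiers per (gene, cluster).

    A tier-t record survives if its conditional BF meets the tier-t cutoff
    and every lower tier of the same probe cluster survived (the
    conditioning set must itself be significant).
    """
    keep_rows = []
    for (_, _), grp in records.groupby(["GENE", "CLUSTER"]):
        grp = grp.sort_values("TIER")
        for _, rec in grp.iterrows():
            cut = cutoffs.get(int(rec["TIER"]))
            if cut is None or rec["MBF"] < cut:
                break
            keep_rows.append(rec)
    if not keep_rows:
        return records.iloc[0:0]
    return pd.DataFrame(keep_rows).reset_index(drop=True)


def run_pipeline(config: PipelineConfig,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Run the full analysis on a fresh synthetic study set."""
    cfg = config
    prior = PriorGrid(sigma_a=tuple(cfg.prior_sigma_a))
    study = simulate_study_set(
        n_genes=cfg.n_genes, n_snps_per_gene=cfg.n_snps_per_gene,
        n_samples=cfg.n_samples, snp_spacing=cfg.snp_spacing,
        hotspot_every=cfg.hotspot_every, hotspot_rate=cfg.hotspot_rate,
        background_rate=cfg.background_recomb_rate,
        maf_range=(cfg.maf_low, cfg.maf_high),
        within_block_r2=cfg.within_block_r2, eqtl_fraction=cfg.eqtl_fraction,
        two_tier_fraction=cfg.two_tier_fraction, beta=cfg.effect_size,
        effect_r2=cfg.effect_r2,
        n_confounders=cfg.n_confounders,
        confounder_var_frac=cfg.confounder_var_frac, noise_sd=cfg.noise_sd,
        specific_fraction=cfg.cre_specific_fraction,
        eqtl_enrichment=cfg.cre_eqtl_enrichment,
        cre_background_rate=cfg.cre_background_rate,
        missing_fraction=cfg.missing_fraction, n_gwas=cfg.n_gwas,
        seed=cfg.seed)

    # --- preprocess each study to residual traits
    residuals, reports = {}, {}
    for sid, intens in study.expression.items():
        residuals[sid], reports[sid] = residualize_study(
            intens, knn_k=cfg.knn_k, pve_delta=cfg.pve_delta)

    blocks = {c: ld_blocks(r, cfg.rate_threshold).block_index
              for c, r in study.rmaps.items()}
    gene_means = {sid: np.log2(study.expression[sid]).mean()
                  for sid in study.expression}

    # --- discovery scan + permutation FDR
    fdr, records_all = permutation_fdr(
        residuals["A_discovery"], study.genotypes["A_discovery"],
        study.gene_models, blocks, prior,
        seed=cfg.seed + 1, n_perm=cfg.n_perm, max_tiers=cfg.max_tiers)
    # fill GEX with the discovery-study mean intensity per gene
    gm_means = gene_means["A_discovery"]
    records_all["GEX"] = records_all["GENE"].map(gm_means).astype(float)
    cutoffs = {t: fdr.cutoff_at(cfg.fdr_target, tier=t)
               for t in range(1, cfg.max_tiers + 1)}
    records = significant_records(records_all, cutoffs)

    # --- replication in the within- and between-cell-type targets
    targets = {
        sid: target_association_table(residuals[sid], study.genotypes[sid],
                                      records, prior)
        for sid in ("A_replication", "B_paired")
    }
    replication = call_replication(records, targets,
                                   within_study="A_replication",
                                   between_study="B_paired",
                                   bf_threshold=cfg.replication_bf_threshold,
                                   maf_min=cfg.maf_min)

    # --- CRE overlap + enrichment models
    snp_map = study.snp_map()
    annotation = annotate_snps(snp_map, study.tracks, pad=cfg.pad)
    bg = background_snps(snp_map, study.gene_models, seed=cfg.seed + 7)
    # at small problem sizes a sparse class can separate a logistic model;
    # the pipeline records what fits and skips what does not
    enrichment = {}

    def _try_fit(key, model_id, table):
        if table is None:
            return None
        try:
            fit = fit_enrichment(model_id, table)
        except (RuntimeError, ValueError):
            # separation or a degenerate (e.g. all-zero) covariate at small
            # problem sizes; the model is not identifiable there
            return None
        enrichment[key] = fit.params
        return fit

    _try_fit("eq2_activating", "eq2",
             _eq2_table(records, bg, annotation, snp_map, study.gene_models,
                        gm_means, "activating_A"))
    _try_fit("eq2_repressive", "eq2",
             _eq2_table(records, bg, annotation, snp_map, study.gene_models,
                        gm_means, "repressive_A"))
    _try_fit("eq3", "eq3", _eq3_table(replication, annotation, "activating_A"))
    fit4 = _try_fit("eq4", "eq4",
                    _eq4_table(records, bg, annotation, snp_map,
                               study.gene_models, gm_means, "activating_A"))
    if fit4 is not None:
        enrichment["eq4_tier_diff"] = pd.DataFrame([fit4.extras["tier_diff"]])
    hs = hotspot_intervals(study.rmaps, cfg.rate_threshold)
    pairs = build_snp_pairs(records, bg, study.gene_models, hs, snp_map,
                            seed=cfg.seed + 11)
    _try_fit("eq5", "eq5", _eq5_table(pairs, study.tracks["insulator_A"],
                                      study.gene_models))

    # --- bivariate classification (A_discovery vs paired B)
    top = records[records["TIER"] == 1]
    bivariate, bivariate_summary = classify_bivariate_batch(
        residuals["A_discovery"], residuals["B_paired"],
        study.genotypes["A_discovery"], study.genotypes["B_paired"],
        top, prior)

    # --- replication prediction (random forest)
    classifier = {}
    tested = replication[replication["category"] != "untested"]
    cre_cols = list(study.tracks.keys()) + [f"intervening_insulator_{ct}"
                                            for ct in ("A", "B")]
    tss_of = study.gene_models.set_index("gene_id")["tss"]
    insulator_flags = pd.DataFrame({"snp_id": tested["RSID"].to_numpy()})
    for ct in ("A", "B"):
        track = study.tracks[f"insulator_{ct}"]
        insulator_flags[f"intervening_insulator_{ct}"] = intervening_flags(
            tested["RSCOORD"].to_numpy(),
            tss_of.loc[tested["GENE"]].to_numpy(),
            tested["CHR"].to_numpy(), track.intervals).astype(int)
    insulator_flags = insulator_flags.drop_duplicates("snp_id")
    if len(tested) >= 40:
        labels = {
            "within": (tested["status_A_replication"] == "replicated"),
            "between": (tested["status_B_paired"] == "replicated"),
            "cell_specific": (tested["category"] == "cell-specific"),
        }
        for task, lab in labels.items():
            if lab.nunique() < 2:
                continue
            rows = assemble_features(tested, annotation, lab.astype(int),
                                     insulator_flags=insulator_flags)
            rep_with, rep_without, delta = ablate_cre_features(
                rows, cre_cols, k=cfg.cv_folds, n_trees=cfg.n_trees,
                seed=cfg.seed + 13)
            classifier[task] = {
                "auc": rep_with.auc, "accuracy": rep_with.accuracy,
                "auc_without_cre": rep_without.auc, "delta_auc": delta,
                "top_features": rep_with.importance.head(5).to_dict(),
            }

    # --- GWAS transfer with the reduced CRE feature set
    gwas = _gwas_transfer(study, records, bg, snp_map, cfg)

    result = PipelineResult(
        config=cfg, study=study, residuals=residuals,
        records_all=records_all, fdr_table=fdr.table, cutoffs=cutoffs,
        records=records, replication=replication, enrichment=enrichment,
        bivariate=bivariate, bivariate_summary=bivariate_summary,
        classifier=classifier, gwas=gwas)
    if outdir is not None:
        _write_outputs(result, Path(outdir), reports)
    return result


def _tss_dist(snp_pos: np.ndarray, genes: pd.Series,
              gene_models: pd.DataFrame) -> np.ndarray:
    tss = gene_models.set_index("gene_id")["tss"]
    return snp_pos - tss.loc[genes].to_numpy()


def _eq2_table(records, background, annotation, snp_map, gene_models,
               gene_means, track_id) -> pd.DataFrame:
    ann = annotation.set_index("snp_id")
    e = pd.DataFrame({
        "overlap": ann.loc[records["RSID"], track_id].to_numpy(),
        "tss_dist_signed": records["TSS_DIST"].to_numpy(dtype=float),
        "expression": records["GEX"].to_numpy(dtype=float),
        "is_eqtl": 1.0,
    })
    bpos = background["pos"].to_numpy()
    b = pd.DataFrame({
        "overlap": ann.loc[background["snp_id"], track_id].to_numpy(),
        "tss_dist_signed": _tss_dist(bpos, background["gene_id"], gene_models),
        "expression": background["gene_id"].map(gene_means).to_numpy(dtype=float),
        "is_eqtl": 0.0,
    })
    out = pd.concat([e, b], ignore_index=True)
    out["tss_dist_abs"] = out["tss_dist_signed"].abs()
    return out


def _eq3_table(replication, annotation, track_id) -> pd.DataFrame | None:
    tested = replication[replication["status_A_replication"] != "untested"]
    if len(tested) < 20:
        return None
    ann = annotation.set_index("snp_id")
    out = pd.DataFrame({
        "replicated": (tested["status_A_replication"] == "replicated").astype(float).to_numpy(),
        "overlap": ann.loc[tested["RSID"], track_id].to_numpy(dtype=float),
        "tss_dist_signed": tested["TSS_DIST"].to_numpy(dtype=float),
        "log10bf": tested["MBF"].to_numpy(dtype=float),
        "tier": tested["TIER"].to_numpy(dtype=float),
    })
    out["tss_dist_abs"] = out["tss_dist_signed"].abs()
    if out["replicated"].nunique() < 2:
        return None
    return out


def _eq4_table(records, background, annotation, snp_map, gene_models,
               gene_means, track_id) -> pd.DataFrame:
    base = _eq2_table(records, background, annotation, snp_map, gene_models,
                      gene_means, track_id)
    tiers = np.concatenate([records["TIER"].to_numpy(),
                            np.zeros(len(background), dtype=int)])
    base["is_tier1"] = (tiers == 1).astype(float)
    base["is_tier2"] = (tiers >= 2).astype(float)
    return base.drop(columns=["is_eqtl"])


def _eq5_table(pairs, insulator_track, gene_models) -> pd.DataFrame | None:
    if len(pairs) == 0 or (pairs["source"] == "eqtl-tier1-tier2").sum() < 5:
        return None
    from .overlap import intervening_flags
    tss = gene_models.set_index("gene_id")["tss"]
    gtss = tss.loc[pairs["gene_id"]].to_numpy()
    out = pd.DataFrame({
        "intervening": intervening_flags(
            pairs["pos_a"].to_numpy(), pairs["pos_b"].to_numpy(),
            pairs["chrom"].to_numpy(), insulator_track.intervals).astype(float),
        "distance": pairs["distance"].to_numpy(dtype=float),
        "tss_dist_a": pairs["pos_a"].to_numpy() - gtss,
        "tss_dist_b": pairs["pos_b"].to_numpy() - gtss,
        "hotspot": pairs["hotspot"].astype(float).to_numpy(),
        "intervening_tss": pairs["intervening_tss"].astype(float).to_numpy(),
        "is_eqtl_pair": (pairs["source"] == "eqtl-tier1-tier2").astype(float).to_numpy(),
    })
    if out["intervening"].nunique() < 2:
        return None
    return out


def _gwas_transfer(study: StudySet, records: pd.DataFrame,
                   background: pd.DataFrame, snp_map: pd.DataFrame,
                   cfg: PipelineConfig) -> dict:
    """Reduced-CRE-feature eQTL-vs-background forest, applied to GWAS SNPs."""
    rng = np.random.default_rng(cfg.seed + 17)
    classes = ("activating", "repressive", "insulator")

    def class_features(snps: pd.DataFrame, celltype: str) -> pd.DataFrame:
        out = pd.DataFrame(index=range(len(snps)))
        for cls in classes:
            track = study.tracks[f"{cls}_{celltype}"]
            out[cls] = snp_overlaps(snps[["chrom", "pos"]].reset_index(drop=True),
                                    track, pad=cfg.pad).astype(float)
        return out

    pos_records = records[records["TIER"] == 1]
    if len(pos_records) < 10:
        return {"skipped": "too few discovery eQTLs"}
    pos_of = snp_map.set_index("snp_id")
    pos_snps = pos_of.loc[pos_records["RSID"]][["chrom", "pos"]].reset_index()
    eqtl_ids = set(records["RSID"])
    neg_pool = background[~background["snp_id"].isin(eqtl_ids)]
    n_neg = min(len(neg_pool), len(pos_snps))
    neg_snps = neg_pool.iloc[
        rng.choice(len(neg_pool), size=n_neg, replace=False)
    ][["snp_id", "chrom", "pos"]].reset_index(drop=True)

    train = pd.concat([
        class_features(pos_snps, "A").assign(label=1),
        class_features(neg_snps, "A").assign(label=0),
    ], ignore_index=True)
    train["snp_id"] = list(pos_snps["snp_id"]) + list(neg_snps["snp_id"])
    train["gene_id"] = ""

    gwas = study.gwas
    matched = class_features(gwas, "B")
    unmatched = class_features(gwas, "A")
    res = annotate_gwas(train, matched, unmatched, n_trees=cfg.n_trees,
                        seed=cfg.seed + 19)
    return {"wilcoxon_p": res["wilcoxon_p"],
            "median_shift": res["median_shift"],
            "mean_p_matched": float(np.mean(res["p_matched"])),
            "mean_p_unmatched": float(np.mean(res["p_unmatched"]))}


def _write_outputs(result: PipelineResult, outdir: Path, reports: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    study = result.study
    eio.write_gene_models(study.gene_models, outdir / "gene_models.tsv")
    eio.write_snp_map(study.snp_map(), outdir / "snp_map.tsv")
    study.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False,
                       float_format="%.6g")
    for sid, expr in study.expression.items():
        eio.write_expression_tsv(expr, outdir / f"expression_{sid}.tsv")
    for sid, res in result.residuals.items():
        eio.write_expression_tsv(res, outdir / f"residuals_{sid}.tsv",
                                 stage="residual")
    for tid, track in study.tracks.items():
        eio.write_bed(track.intervals, outdir / f"track_{tid}.bed", name=tid)
    study.gwas.to_csv(outdir / "gwas_snps.tsv", sep="\t", index=False)
    result.records_all.assign(REF_STUDY="A_discovery").to_csv(
        outdir / "eqtl_records_all.tsv", sep="\t", index=False,
        float_format="%.6g")
    result.records.assign(REF_STUDY="A_discovery").to_csv(
        outdir / "eqtl_records_significant.tsv", sep="\t", index=False,
        float_format="%.6g")
    result.fdr_table.to_csv(outdir / "fdr_table.tsv", sep="\t", index=False,
                            float_format="%.6g")
    result.replication.to_csv(outdir / "replication.tsv", sep="\t", index=False,
                              float_format="%.6g")
    for mid, params in result.enrichment.items():
        params.to_csv(outdir / f"enrichment_{mid}.tsv", sep="\t",
                      float_format="%.6g")
    result.bivariate.to_csv(outdir / "bivariate.tsv", sep="\t", index=False,
                            float_format="%.6g")
    result.bivariate_summary.to_csv(outdir / "bivariate_summary.tsv", sep="\t",
                                    index=False, float_format="%.6g")
    eio.write_json({
        "config": result.config.to_dict(),
        "config_digest": result.config.digest(),
        "normalization": reports,
        "cutoffs": {str(k): v for k, v in result.cutoffs.items()},
        "classifier": result.classifier,
        "gwas": result.gwas,
    }, outdir / "run_report.json")
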