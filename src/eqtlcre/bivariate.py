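"""Five-model bivariate Bayesian regression over paired cell types.

For a gene-SNP pair measured in two cell types A and B, five association
models are compared with the joint null (no eQTL in either cell type):

* ``stable``       - one shared effect in both cell types;
* ``A-not-B``      - an effect in A only;
* ``B-not-A``      - an effect in B only;
* ``A-and-B``      - independent effects in A and B;
* ``A-opposite-B`` - shared magnitude, opposite sign.

Cell-type likelihoods are treated as independent (the paired-residual
correlation is ignored), so the single-cell-type models factor into
univariate Bayes factors, and the shared-effect models are conjugate
regressions on the stacked data with per-cell-type intercepts.  The
integrated Bayes factor summarizing evidence for a *differential* eQTL is

    iBF = log10( mean(BF_AnotB, BF_BnotA, BF_AandB, BF_AoppB) / BF_stable )

and a pair is flagged differential when iBF > 0 (more evidence for any
differential configuration than for a stable eQTL).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .bayes import (LN10, PriorGrid, _center, _grid_log10bf,
                    dominance_encoding, univariate_log10bf)

DIFFERENTIAL_MODELS = ("A-not-B", "B-not-A", "A-and-B", "A-opposite-B")

__all__ = [
    "BivariateResult",
    "fit_five_models",
    "integrated_bf",
    "classify_bivariate_batch",
    "DIFFERENTIAL_MODELS",
]


@dataclass
class BivariateResult:
    """Per-model log10 BFs, integrated BF and best-model call for one pair."""

    gene_id: str
    snp_id: str
    log10_bf: dict  # model -> log10 BF vs joint null
    ibf: float = field(default=np.nan)
    best_model: str | None = None
    differential: bool = False


def _stacked_log10bf(yA, yB, gA, gB, prior: PriorGrid, flip_b: bool) -> float:
    """Shared-effect BF on stacked data with per-cell-type intercepts."""
    y = np.concatenate([yA, yB])
    add = np.concatenate([gA, -gB if flip_b else gB])
    dom = np.concatenate([dominance_encoding(gA), dominance_encoding(gB)])
    strata = np.concatenate([np.zeros(len(yA), dtype=int),
                             np.ones(len(yB), dtype=int)])
    yc, Xc, q = _center(y, np.column_stack([add, dom]), strata)
    return _grid_log10bf(yc, Xc[:, :1], Xc[:, 1:], q, prior)


def fit_five_models(yA: np.ndarray, yB: np.ndarray, gA: np.ndarray,
                    gB: np.ndarray, prior: PriorGrid | None = None,
                    gene_id: str = "", snp_id: str = "") -> BivariateResult:
    """Fit the five bivariate models and integrate their Bayes factors.

    Swapping the (yA, gA) and (yB, gB) arguments swaps the A-not-B and
    B-not-A Bayes factors exactly and leaves the symmetric models unchanged.
    """
    prior = prior or PriorGrid()
    yA = np.asarray(yA, dtype=float)
    yB = np.asarray(yB, dtype=float)
    gA = np.asarray(gA, dtype=float)
    gB = np.asarray(gB, dtype=float)
    if np.var(gA) == 0 or np.var(gB) == 0:
        raise ValueError("monomorphic genotype")
    bf_a = univariate_log10bf(yA, gA, prior)
    bf_b = univariate_log10bf(yB, gB, prior)
    log10_bf = {
        "A-not-B": bf_a,
        "B-not-A": bf_b,
        "A-and-B": bf_a + bf_b,
        "stable": _stacked_log10bf(yA, yB, gA, gB, prior, flip_b=False),
        "A-opposite-B": _stacked_log10bf(yA, yB, gA, gB, prior, flip_b=True),
    }
    result = BivariateResult(gene_id, snp_id, log10_bf)
    return integrated_bf(result)


def integrated_bf(result: BivariateResult) -> BivariateResult:
    """Fill in the integrated BF, differential flag, and best-model label.

    iBF = log10(mean of the four differential BFs) - log10(BF_stable); the
    differential flag requires strict iBF > 0, and the best model is the
    argmax over the four differential models when flagged, else "stable".
    """
    diff_ln = np.array([result.log10_bf[m] for m in DIFFERENTIAL_MODELS]) * LN10
    mean_ln = logsumexp(diff_ln) - np.log(len(DIFFERENTIAL_MODELS))
    result.ibf = float(mean_ln / LN10 - result.log10_bf["stable"])
    result.differential = result.ibf > 0
    if result.differential:
        result.best_model = max(DIFFERENTIAL_MODELS,
                                key=lambda m: result.log10_bf[m])
    else:
        result.best_model = "stable"
    return result


def classify_bivariate_batch(traits_a: pd.DataFrame, traits_b: pd.DataFrame,
                             genotypes_a: dict, genotypes_b: dict,
                             records: pd.DataFrame,
                             prior: PriorGrid | None = None,
                             pooled: bool = False
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every discovery eQTL record in two paired cell types.

    ``traits_*`` are residual trait matrices (columns keyed like the record
    GENE or CLUSTER ids); ``genotypes_*`` map chromosome -> GenotypeMatrix.
    Sample sets must be identical (same individuals in both cell types)
    unless ``pooled=True`` acknowledges the pooled-sample approximation.
    Returns (per-record results table, per-class composition summary).
    """
    prior = prior or PriorGrid()
    if list(traits_a.index) != list(traits_b.index) and not pooled:
        raise ValueError("unpaired sample sets; pass pooled=True to approximate")
    rows = []
    for _, rec in records.iterrows():
        gene = rec["GENE"]
        trait_key = rec["CLUSTER"] if rec.get("CLUSTER") in traits_a.columns else gene
        if trait_key not in traits_a.columns or trait_key not in traits_b.columns:
            continue
        gt_a = genotypes_a[rec["CHR"]]
        gt_b = genotypes_b[rec["CHR"]]
        ja = gt_a.snp_ids.index(rec["RSID"])
        jb = gt_b.snp_ids.index(rec["RSID"])
        res = fit_five_models(traits_a[trait_key].to_numpy(),
                              traits_b[trait_key].to_numpy(),
                              gt_a.dosages[:, ja], gt_b.dosages[:, jb],
                              prior, gene_id=gene, snp_id=rec["RSID"])
        rows.append({
            "gene_id": gene, "snp_id": rec["RSID"],
            "tss_dist": rec.get("TSS_DIST", np.nan),
            **{f"bf_{m}": res.log10_bf[m] for m in
               ("stable",) + DIFFERENTIAL_MODELS},
            "ibf": res.ibf, "best_model": res.best_model,
            "differential": res.differential,
        })
    results = pd.DataFrame(rows)
    if len(results):
        summary = results.groupby("best_model").agg(
            n=("gene_id", "size"),
            median_ibf=("ibf", "median"),
            median_abs_tss_dist=("tss_dist", lambda s: np.nanmedian(np.abs(s))),
        ).reset_index()
    else:
        summary = pd.DataFrame(columns=["best_model", "n", "median_ibf",
                                        "median_abs_tss_dist"])
    return results, summary
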