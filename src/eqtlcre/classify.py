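"""Random-forest prediction of eQTL replication and cell-type specificity.

Feature rows combine discovery statistics (log10 BF, effect size, TSS
distance, gene expression level) with per-track CRE overlap flags for the
matched and unmatched cell types.  Cross-validated out-of-fold
probabilities give ROC/AUC (via the rank statistic), accuracy at 0.5, and
per-feature permutation importance.  A reduced-feature variant transfers to
GWAS SNP lists: the forest trained to separate eQTL from background SNPs is
applied with CRE features from a matched vs an unmatched cell type and the
probability shift is tested by Wilcoxon's signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ClassifierReport",
    "assemble_features",
    "rank_auc",
    "cross_validate_rf",
    "ablate_cre_features",
    "annotate_gwas",
]

META_COLUMNS = ("snp_id", "gene_id", "label")


@dataclass
class ClassifierReport:
    auc: float
    accuracy: float
    roc: pd.DataFrame               # fpr, tpr
    importance: pd.Series           # per-feature mean accuracy drop
    fold_assignments: np.ndarray
    oof_probabilities: np.ndarray
    seed: int


def assemble_features(records: pd.DataFrame, annotation: pd.DataFrame,
                      labels: pd.Series,
                      insulator_flags: pd.DataFrame | None = None
                      ) -> pd.DataFrame:
    """One feature row per discovery record.

    ``annotation`` is the 0/1 SNP x track matrix from
    :func:`eqtlcre.overlap.annotate_snps`; ``labels`` is a binary outcome
    aligned to ``records`` rows (e.g. a replication status or an
    eQTL-vs-background indicator).
    """
    ann = annotation.set_index("snp_id").drop(columns=["chrom", "pos"],
                                              errors="ignore")
    missing = set(records["RSID"]) - set(ann.index)
    if missing:
        raise ValueError(f"records lack annotation for {len(missing)} SNPs")
    rows = ann.loc[records["RSID"]].reset_index(drop=True)
    feat = pd.DataFrame({
        "snp_id": records["RSID"].to_numpy(),
        "gene_id": records["GENE"].to_numpy(),
        "log10bf": records["UBF"].to_numpy(dtype=float),
        "beta": records["BETA"].to_numpy(dtype=float),
        "tss_dist_signed": records["TSS_DIST"].to_numpy(dtype=float),
        "tss_dist_abs": np.abs(records["TSS_DIST"].to_numpy(dtype=float)),
        "expression": records["GEX"].to_numpy(dtype=float),
    })
    feat = pd.concat([feat, rows], axis=1)
    if insulator_flags is not None:
        ins = insulator_flags.set_index("snp_id")
        for col in ins.columns:
            feat[col] = ins.loc[feat["snp_id"], col].to_numpy()
    feat["label"] = np.asarray(labels).astype(int)
    if feat.drop(columns=["snp_id", "gene_id"]).isna().any().any():
        raise ValueError("feature rows contain missing values")
    return feat


def rank_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank formulation (ties get average rank)."""
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both classes for AUC")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def _feature_columns(rows: pd.DataFrame) -> list[str]:
    return [c for c in rows.columns if c not in META_COLUMNS]


def cross_validate_rf(rows: pd.DataFrame, k: int = 10, n_trees: int = 500,
                      seed: int = 0,
                      feature_columns: list[str] | None = None
                      ) -> ClassifierReport:
    """Stratified k-fold random-forest cross-validation.

    Out-of-fold predicted probabilities are pooled for the ROC/AUC; accuracy
    uses a fixed probability threshold of 0.5.  Permutation importance is
    the mean drop in held-out accuracy when one feature column is permuted,
    averaged over folds.
    """
    cols = feature_columns or _feature_columns(rows)
    X = rows[cols].to_numpy(dtype=float)
    y = rows["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present")
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.zeros(len(y))
    folds = np.zeros(len(y), dtype=int)
    importance = pd.Series(0.0, index=cols)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed + fold,
                                     n_jobs=1)
        clf.fit(X[tr], y[tr])
        proba = clf.predict_proba(X[te])[:, list(clf.classes_).index(1)]
        oof[te] = proba
        folds[te] = fold
        base_acc = np.mean((proba >= 0.5).astype(int) == y[te])
        for j, col in enumerate(cols):
            Xp = X[te].copy()
            Xp[:, j] = Xp[rng.permutation(len(te)), j]
            pp = clf.predict_proba(Xp)[:, list(clf.classes_).index(1)]
            importance[col] += base_acc - np.mean((pp >= 0.5).astype(int) == y[te])
    importance /= k
    auc = rank_auc(y, oof)
    fpr, tpr, _ = roc_curve(y, oof)
    accuracy = float(np.mean((oof >= 0.5).astype(int) == y))
    return ClassifierReport(auc=auc, accuracy=accuracy,
                            roc=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
                            importance=importance.sort_values(ascending=False),
                            fold_assignments=folds, oof_probabilities=oof,
                            seed=seed)


def ablate_cre_features(rows: pd.DataFrame, cre_columns: list[str],
                        k: int = 10, n_trees: int = 500, seed: int = 0
                        ) -> tuple[ClassifierReport, ClassifierReport, float]:
    """Train with and without CRE columns on identical folds; report the AUC gap.

    Returns (report_with, report_without, delta_auc).
    """
    all_cols = _feature_columns(rows)
    without = [c for c in all_cols if c not in cre_columns]
    rep_with = cross_validate_rf(rows, k=k, n_trees=n_trees, seed=seed,
                                 feature_columns=all_cols)
    rep_without = cross_validate_rf(rows, k=k, n_trees=n_trees, seed=seed,
                                    feature_columns=without)
    return rep_with, rep_without, rep_with.auc - rep_without.auc


def annotate_gwas(train_rows: pd.DataFrame, gwas_matched: pd.DataFrame,
                  gwas_unmatched: pd.DataFrame, n_trees: int = 500,
                  seed: int = 0) -> dict:
    """Transfer an eQTL-vs-background forest to GWAS SNPs via cell-proxy CREs.

    ``train_rows`` hold the reduced shared feature set with an
    eQTL-vs-background label; ``gwas_matched`` / ``gwas_unmatched`` are the
    same feature columns computed for the GWAS SNPs from the
    disease-relevant (matched) and an unrelated (unmatched) cell type's
    tracks.  Returns per-SNP probabilities under both track sets and the
    two-sided Wilcoxon signed-rank p for a matched-vs-unmatched shift.
    """
    cols = _feature_columns(train_rows)
    for frame, name in ((gwas_matched, "matched"), (gwas_unmatched, "unmatched")):
        missing = set(cols) - set(frame.columns)
        if missing:
            raise ValueError(f"{name} GWAS features missing columns {missing}")
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    clf.fit(train_rows[cols].to_numpy(dtype=float),
            train_rows["label"].to_numpy(dtype=int))
    pos = list(clf.classes_).index(1)
    p_match = clf.predict_proba(gwas_matched[cols].to_numpy(dtype=float))[:, pos]
    p_un = clf.predict_proba(gwas_unmatched[cols].to_numpy(dtype=float))[:, pos]
    diff = p_match - p_un
    if np.allclose(diff, 0.0):
        pval = 1.0
    else:
        pval = float(stats.wilcoxon(p_match, p_un,
                                    alternative="two-sided").pvalue)
    return {"p_matched": p_match, "p_unmatched": p_un,
            "median_shift": float(np.median(diff)), "wilcoxon_p": pval}
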