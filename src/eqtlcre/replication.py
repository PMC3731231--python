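"""Cross-study replication, cell-type-specificity calls, binned replication
curves, paired/unpaired categorical tests, and the logistic enrichment models.

A discovery gene-SNP association is *replicated* in a target study when the
target log10 Bayes factor meets a threshold; only pairs tested in the target
(present, with adequate minor allele frequency in both studies) enter the
denominators.  A *cell-type-specific* eQTL replicates in an independent
study of the same cell type but not in a study of a different cell type.

Four logistic enrichment models are provided:

* ``eq2`` - probability of CRE overlap vs an eQTL/background indicator,
  controlling for SNP position and gene expression level;
* ``eq3`` - probability of within-cell-type replication vs CRE overlap,
  controlling for position, discovery BF, and tier;
* ``eq4`` - CRE overlap vs a three-level background/tier-1/tier-2 group,
  with a Wald test of the tier-1 vs tier-2 coefficient difference;
* ``eq5`` - probability of an intervening insulator for SNP pairs vs an
  eQTL-pair/background-pair indicator, controlling for inter-SNP distance,
  pair positions and intervening hotspot/TSS flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "call_replication",
    "binned_curve",
    "mcnemar_test",
    "fisher_test",
    "EnrichmentFit",
    "fit_enrichment",
]

POSITION_SCALE = 1e6  # logistic-model distances are reported per Mb


def call_replication(discovery: pd.DataFrame, targets: dict[str, pd.DataFrame],
                     within_study: str, between_study: str,
                     bf_threshold: float = 1.0,
                     maf_min: float = 0.05) -> pd.DataFrame:
    """Replication status per discovery record and derived specificity category.

    ``discovery`` is a tier-scan record table (columns GENE, RSID, MAF, ...);
    each target table needs columns gene_id, snp_id, log10bf, maf.  Status is
    one of replicated / not-replicated / untested; the category is computed
    only from pairs tested in both the within- and between-cell-type targets.
    """
    out = discovery.copy().reset_index(drop=True)
    for name, table in targets.items():
        keyed = table.set_index(["gene_id", "snp_id"])
        status = []
        for _, rec in out.iterrows():
            key = (rec["GENE"], rec["RSID"])
            if key not in keyed.index or rec["MAF"] < maf_min:
                status.append("untested")
                continue
            row = keyed.loc[key]
            if isinstance(row, pd.DataFrame):
                row = row.iloc[0]
            if float(row["maf"]) < maf_min:
                status.append("untested")
                continue
            status.append("replicated" if float(row["log10bf"]) >= bf_threshold
                          else "not-replicated")
        out[f"status_{name}"] = status
    w = out[f"status_{within_study}"]
    b = out[f"status_{between_study}"]
    cat = np.where((w == "untested") | (b == "untested"), "untested",
          np.where((w == "replicated") & (b == "replicated"), "within-and-between",
          np.where((w == "replicated") & (b == "not-replicated"), "cell-specific",
          np.where((w == "not-replicated") & (b == "replicated"), "between-only",
                   "neither"))))
    out["category"] = cat
    return out


def binned_curve(x: np.ndarray, outcomes: np.ndarray,
                 n_bins: int = 30) -> pd.DataFrame:
    """Per-bin success fraction with Wilson 95% interval over equal-width bins.

    Empty bins are emitted with NaN fraction and ``empty=True``.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = np.asarray(x, dtype=float)
    outcomes = np.asarray(outcomes).astype(bool)
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    idx = np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = idx == b
        n = int(m.sum())
        if n == 0:
            rows.append((b, (edges[b] + edges[b + 1]) / 2, 0, np.nan,
                         np.nan, np.nan, True))
            continue
        k = int(outcomes[m].sum())
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        rows.append((b, (edges[b] + edges[b + 1]) / 2, n, k / n,
                     float(lo), float(hi), False))
    return pd.DataFrame(rows, columns=["bin", "center", "n", "fraction",
                                       "ci_low", "ci_high", "empty"])


def mcnemar_test(a: np.ndarray, b: np.ndarray) -> float:
    """Exact-binomial two-sided McNemar p on the discordant counts."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("paired vectors must share shape")
    b10 = int(np.sum(a & ~b))
    b01 = int(np.sum(~a & b))
    n = b10 + b01
    if n == 0:
        return 1.0
    return float(stats.binomtest(b10, n, 0.5).pvalue)


def fisher_test(table: np.ndarray) -> tuple[float, float]:
    """Two-sided Fisher's exact test; returns (sample odds ratio, p).

    The sample OR is ad/bc (NaN when undefined); a zero margin gives p = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.rint(t)):
        raise ValueError("need a 2x2 table of non-negative integers")
    a, b = t[0]
    c, d = t[1]
    if b * c == 0:
        orr = np.inf if a * d > 0 else np.nan
    else:
        orr = (a * d) / (b * c)
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins):
        return (np.nan, 1.0)
    _, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
    return (float(orr), float(p))


@dataclass
class EnrichmentFit:
    """Coefficients of a fitted logistic enrichment model."""

    model_id: str
    params: pd.DataFrame  # index = term; columns coef, se, z, p
    aic: float
    extras: dict

    def coef(self, term: str) -> float:
        return float(self.params.loc[term, "coef"])

    def pvalue(self, term: str) -> float:
        return float(self.params.loc[term, "p"])


_MODEL_SPECS = {
    "eq2": {"outcome": "overlap",
            "terms": ["tss_dist_signed", "tss_dist_abs", "expression", "is_eqtl"]},
    "eq3": {"outcome": "replicated",
            "terms": ["overlap", "tss_dist_signed", "tss_dist_abs", "log10bf",
                      "tier"]},
    "eq4": {"outcome": "overlap",
            "terms": ["tss_dist_signed", "tss_dist_abs", "expression",
                      "is_tier1", "is_tier2"]},
    "eq5": {"outcome": "intervening",
            "terms": ["distance", "tss_dist_a", "tss_dist_b", "hotspot",
                      "intervening_tss", "is_eqtl_pair"]},
}


def fit_enrichment(model_id: str, table: pd.DataFrame) -> EnrichmentFit:
    """Fit one of the four logistic enrichment models by IRLS.

    Distance covariates are expected in bp and are rescaled to Mb
    internally; the binary outcome column and covariates must match the
    model spec (see module docstring).  Detected separation / non-convergence
    raises with a diagnostic.
    """
    if model_id not in _MODEL_SPECS:
        raise ValueError(f"unknown enrichment model {model_id!r}")
    spec = _MODEL_SPECS[model_id]
    y = table[spec["outcome"]].astype(float).to_numpy()
    if not np.all(np.isin(y, [0.0, 1.0])):
        raise ValueError("outcome must be binary")
    X = pd.DataFrame(index=table.index)
    for term in spec["terms"]:
        col = table[term].astype(float)
        if term.startswith("tss_dist") or term == "distance":
            col = col / POSITION_SCALE
        X[term] = col
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        import warnings
        with warnings.catch_warnings():
            # statsmodels warns on near-separation; we check the SEs below
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=200, tol=1e-10)
    except Exception as exc:  # perfect separation raises inside IRLS
        raise RuntimeError(f"logistic fit failed ({model_id}): {exc}") from exc
    if np.any(~np.isfinite(res.bse)) or np.any(res.bse > 1e4):
        raise RuntimeError(
            f"logistic fit unstable ({model_id}); possible separation")
    params = pd.DataFrame({
        "coef": res.params, "se": res.bse,
        "z": res.params / res.bse,
        "p": 2 * stats.norm.sf(np.abs(res.params / res.bse)),
    })
    extras: dict = {}
    if model_id == "eq4":
        # Wald test of tier-1 vs tier-2 coefficient difference
        names = list(X.columns)
        c = np.zeros(len(names))
        c[names.index("is_tier1")] = 1.0
        c[names.index("is_tier2")] = -1.0
        diff = float(c @ res.params)
        var = float(c @ res.cov_params() @ c)
        z = diff / np.sqrt(var)
        extras["tier_diff"] = {"estimate": diff, "se": float(np.sqrt(var)),
                               "z": float(z),
                               "p": float(2 * stats.norm.sf(abs(z)))}
    return EnrichmentFit(model_id, params, float(res.aic), extras)
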