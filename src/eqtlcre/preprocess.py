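"""Genotype QC and expression normalization / latent-factor removal.

The expression pipeline follows standard eQTL practice: log2 transform with
a floor at half the minimum positive intensity, k-nearest-neighbour
imputation of missing entries, per-array quantile transform to the average
empirical distribution, per-trait transform to standard-normal quantiles,
principal-component removal (the number chosen by a percent-variance-
explained difference rule), and a final per-trait re-normalization.  The
residual traits are exact standard-normal quantile sets, which is what the
Bayes-factor association model downstream assumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .simulate import GenotypeMatrix

__all__ = [
    "ExpressionMatrix",
    "NormalizationReport",
    "filter_genotypes",
    "normalize_expression",
    "remove_pcs",
    "cluster_probes",
    "per_population_normalize",
    "inverse_normal_transform",
]


@dataclass
class ExpressionMatrix:
    """Samples x traits expression values with a processing-stage tag."""

    values: pd.DataFrame  # index = sample ids, columns = trait ids
    stage: str = "raw"    # raw | log | quantile | residual
    populations: pd.Series | None = None  # optional per-sample label

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def trait_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class NormalizationReport:
    pve: list[float]
    n_pcs_removed: int
    pve_delta: float

    def to_dict(self) -> dict:
        return {"pve": list(map(float, self.pve)),
                "n_pcs_removed": int(self.n_pcs_removed),
                "pve_delta": float(self.pve_delta)}


def _hwe_chi2_p(dosages: np.ndarray) -> np.ndarray:
    """HWE chi-square (1 df) p per SNP from rounded genotype counts."""
    g = np.rint(dosages)
    n = np.sum(~np.isnan(g), axis=0).astype(float)
    n0 = np.nansum(g == 0, axis=0).astype(float)
    n1 = np.nansum(g == 1, axis=0).astype(float)
    n2 = np.nansum(g == 2, axis=0).astype(float)
    q = (n1 + 2 * n2) / (2 * np.maximum(n, 1))
    p = 1 - q
    exp = np.stack([p ** 2 * n, 2 * p * q * n, q ** 2 * n])
    obs = np.stack([n0, n1, n2])
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.nansum(np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0), axis=0)
    return stats.chi2.sf(chi2, df=1)


def filter_genotypes(raw: GenotypeMatrix, sample_call_rate_min: float = 0.95,
                     snp_call_rate_min: float = 0.95,
                     hwe_alpha: float = 1e-4) -> GenotypeMatrix:
    """Genotype QC: sample call rate, SNP call rate, HWE filter, mean imputation.

    Samples below the call-rate threshold are removed first; then SNPs below
    the SNP call-rate threshold are dropped (reference-panel imputation is
    out of scope here); then SNPs with HWE chi-square p < ``hwe_alpha`` are
    removed; remaining sporadic missing dosages are mean-imputed per SNP.
    """
    for thr in (sample_call_rate_min, snp_call_rate_min):
        if not (0 <= thr <= 1):
            raise ValueError("call-rate thresholds must lie in [0, 1]")
    dos = raw.dosages.copy()
    sample_cr = np.mean(~np.isnan(dos), axis=1)
    keep_samples = np.flatnonzero(sample_cr >= sample_call_rate_min)
    if len(keep_samples) == 0:
        raise ValueError("all samples removed by call-rate filter")
    gt = raw.subset_samples(keep_samples)
    dos = gt.dosages
    snp_cr = np.mean(~np.isnan(dos), axis=0)
    keep = snp_cr >= snp_call_rate_min
    if hwe_alpha > 0:
        pvals = _hwe_chi2_p(dos)
        keep &= ~(pvals < hwe_alpha)
    gt = gt.subset_snps(np.flatnonzero(keep))
    dos = gt.dosages.copy()
    col_mean = np.nanmean(dos, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(dos))
    dos[nan_r, nan_c] = col_mean[nan_c]
    gt.dosages = dos
    return gt


def inverse_normal_transform(x: np.ndarray) -> np.ndarray:
    """Phi^-1((rank - 0.5)/n), ties broken by average rank."""
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / len(x))


def _knn_impute_columns(vals: np.ndarray, k: int) -> np.ndarray:
    """Impute missing entries per trait from the k nearest trait columns.

    Distance between two columns is the mean squared difference over their
    jointly observed samples.
    """
    out = vals.copy()
    miss_cols = np.flatnonzero(np.isnan(vals).any(axis=0))
    if len(miss_cols) == 0:
        return out
    obs = ~np.isnan(vals)
    for j in miss_cols:
        dj = np.full(vals.shape[1], np.inf)
        for j2 in range(vals.shape[1]):
            if j2 == j:
                continue
            both = obs[:, j] & obs[:, j2]
            if both.sum() < 2:
                continue
            diff = vals[both, j] - vals[both, j2]
            dj[j2] = np.mean(diff ** 2)
        order = np.argsort(dj)
        neighbors = [j2 for j2 in order if np.isfinite(dj[j2])][:k]
        for i in np.flatnonzero(~obs[:, j]):
            donor = [vals[i, j2] for j2 in neighbors if obs[i, j2]]
            out[i, j] = np.mean(donor) if donor else np.nanmean(vals[:, j])
    return out


def _quantile_to_average(vals: np.ndarray) -> np.ndarray:
    """Per-array (row) quantile transform to the average empirical distribution."""
    n_arrays, n_traits = vals.shape
    sorted_vals = np.sort(vals, axis=1)
    reference = sorted_vals.mean(axis=0)
    out = np.empty_like(vals)
    for i in range(n_arrays):
        ranks = stats.rankdata(vals[i], method="average")  # 1..n
        out[i] = np.interp(ranks, np.arange(1, n_traits + 1), reference)
    return out


def normalize_expression(raw: ExpressionMatrix, knn_k: int = 10) -> ExpressionMatrix:
    """Full intensity -> standard-normal-trait normalization pipeline.

    log2 (flooring non-positive entries at half the minimum positive value on
    the array), k-NN imputation, per-array quantile transform to the average
    empirical distribution, then per-trait standard-normal quantile
    transform.  Constant traits are dropped with a warning.
    """
    vals = raw.values.to_numpy(dtype=float).copy()
    if vals.shape[0] < 2 or vals.shape[1] < 2:
        raise ValueError("need >= 2 samples and >= 2 traits")
    # log2 with per-array floor
    for i in range(vals.shape[0]):
        row = vals[i]
        pos = row[np.isfinite(row) & (row > 0)]
        floor = pos.min() / 2.0 if len(pos) else 1.0
        row = np.where(np.isfinite(row) & (row <= 0), floor, row)
        vals[i] = np.where(np.isfinite(row), np.log2(row), np.nan)
    vals = _knn_impute_columns(vals, knn_k)
    cols = list(raw.values.columns)
    const = [j for j in range(vals.shape[1]) if np.ptp(vals[:, j]) == 0]
    if const:
        for j in const:
            warnings.warn(f"trait {cols[j]} is constant; dropped")
        keep_j = [j for j in range(vals.shape[1]) if j not in const]
        vals = vals[:, keep_j]
        cols = [cols[j] for j in keep_j]
    vals = _quantile_to_average(vals)
    keep, out_cols = [], []
    for j in range(vals.shape[1]):
        if np.ptp(vals[:, j]) == 0:
            warnings.warn(f"trait {cols[j]} constant after normalization; dropped")
            continue
        keep.append(inverse_normal_transform(vals[:, j]))
        out_cols.append(cols[j])
    out = pd.DataFrame(np.column_stack(keep), index=raw.values.index,
                       columns=out_cols)
    return ExpressionMatrix(out, stage="quantile", populations=raw.populations)


def remove_pcs(expr: ExpressionMatrix, pve_delta: float = 0.01,
               renormalize: bool = True
               ) -> tuple[ExpressionMatrix, NormalizationReport]:
    """Remove leading expression PCs chosen by the PVE-difference rule.

    PCs 1..k are removed where k is the number of leading components for
    which the drop to the next component's percent variance explained is at
    least ``pve_delta``; residuals are re-quantile-normalized per trait.
    """
    if pve_delta <= 0:
        raise ValueError("pve_delta must be positive")
    if expr.stage not in ("quantile", "residual"):
        raise ValueError("remove_pcs expects quantile-normalized input")
    X = expr.values.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    pve = (s ** 2) / np.sum(s ** 2)
    k = 0
    while k < len(pve) - 1 and (pve[k] - pve[k + 1]) >= pve_delta:
        k += 1
    if k > 0:
        scores = U[:, :k] * s[:k]
        # least-squares residual of each trait on the k PC scores
        coef, *_ = np.linalg.lstsq(scores, Xc, rcond=None)
        resid = Xc - scores @ coef
    else:
        resid = Xc
    if renormalize:
        out = np.column_stack([inverse_normal_transform(resid[:, j])
                               for j in range(resid.shape[1])])
    else:
        out = resid
    res = ExpressionMatrix(pd.DataFrame(out, index=expr.values.index,
                                        columns=expr.values.columns),
                           stage="residual", populations=expr.populations)
    return res, NormalizationReport(pve=list(pve), n_pcs_removed=k,
                                    pve_delta=pve_delta)


def cluster_probes(expr: ExpressionMatrix, probe_to_gene: pd.DataFrame,
                   max_clusters: int = 3, seed: int = 0) -> ExpressionMatrix:
    """Collapse probes to per-gene probe-cluster traits.

    Per gene, probes are embedded on the leading principal components of the
    probes x samples matrix and clustered with a Gaussian mixture; the
    component count (1..max_clusters) is chosen by BIC.  Each cluster's trait
    is the per-sample mean of its member probes; single-probe genes pass
    through unchanged.  ``probe_to_gene`` has columns probe_id, gene_id.
    """
    if max_clusters < 1:
        raise ValueError("max_clusters must be >= 1")
    if expr.stage != "residual":
        raise ValueError("cluster_probes expects residual-stage input")
    vals = expr.values
    out = {}
    for gene_id, grp in probe_to_gene.groupby("gene_id", sort=True):
        probes = [p for p in grp["probe_id"] if p in vals.columns]
        if len(probes) == 0:
            continue
        if len(probes) == 1:
            out[f"{gene_id}.c1"] = vals[probes[0]].to_numpy()
            continue
        M = vals[probes].to_numpy().T  # probes x samples
        d = min(len(probes) - 1, 3)
        Mc = M - M.mean(axis=0)
        _, _, Vt = np.linalg.svd(Mc, full_matrices=False)
        emb = Mc @ Vt[:d].T
        best_labels, best_bic = None, np.inf
        for kk in range(1, min(max_clusters, len(probes)) + 1):
            gmm = GaussianMixture(n_components=kk, covariance_type="spherical",
                                  reg_covar=1e-4, n_init=3, random_state=seed)
            gmm.fit(emb)
            bic = gmm.bic(emb)
            if bic < best_bic - 1e-9:
                best_bic = bic
                best_labels = gmm.predict(emb)
        for ci in range(best_labels.max() + 1):
            members = [probes[i] for i in np.flatnonzero(best_labels == ci)]
            if members:
                out[f"{gene_id}.c{ci + 1}"] = vals[members].to_numpy().mean(axis=1)
    return ExpressionMatrix(pd.DataFrame(out, index=vals.index),
                            stage="residual", populations=expr.populations)


def per_population_normalize(expr: ExpressionMatrix,
                             pop_labels: pd.Series) -> ExpressionMatrix:
    """Per-trait standard-normal quantile transform within each population, pooled."""
    labels = pop_labels.reindex(expr.values.index)
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError("every population needs >= 2 samples")
    vals = expr.values.to_numpy(dtype=float).copy()
    for pop in counts.index:
        rows = np.flatnonzero((labels == pop).to_numpy())
        for j in range(vals.shape[1]):
            vals[rows, j] = inverse_normal_transform(vals[rows, j])
    return ExpressionMatrix(pd.DataFrame(vals, index=expr.values.index,
                                         columns=expr.values.columns),
                            stage=expr.stage, populations=labels)
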