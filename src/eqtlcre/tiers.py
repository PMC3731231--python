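"""LD-block segmentation, tiered independent-SNP discovery (allelic
heterogeneity), forward-stepwise/BIC selection, and permutation FDR.

LD blocks are delimited by inter-SNP intervals whose recombination rate
meets a cM/Mb threshold.  Per gene, the most associated SNP per block (by
univariate log10 Bayes factor) is a candidate; tier 1 is the top candidate
and higher tiers are admitted greedily by conditional (multivariate) BF
given all previously accepted SNPs, each in a distinct block.  The FDR of a
BF cutoff is estimated from a single shared permutation of expression
sample labels, as the ratio of permuted to observed association counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import (PriorGrid, batch_univariate_log10bf, effect_estimate,
                    multivariate_log10bf)
from .simulate import GenotypeMatrix, RecombinationMap, annotate_tss_tes, cis_bounds

RECORD_COLUMNS = ["GENE", "CLUSTER", "CHR", "STRAND", "TSS", "TES", "RSID",
                  "HS_INDEX", "RSCOORD", "TIER", "UBF", "MBF", "BETA", "MAF",
                  "GEX", "TSS_DIST"]

__all__ = [
    "LdBlockMap",
    "FdrTable",
    "ld_blocks",
    "hotspot_intervals",
    "tier_scan",
    "scan_study",
    "forward_stepwise_bic",
    "permutation_fdr",
    "RECORD_COLUMNS",
]


@dataclass
class LdBlockMap:
    """Block index per SNP plus the delimiting interval list."""

    chromosome: str
    block_index: np.ndarray           # per SNP, non-decreasing
    boundaries: list[tuple[int, int]]  # inter-SNP intervals with rate >= threshold

    @property
    def n_blocks(self) -> int:
        return int(self.block_index.max()) + 1 if len(self.block_index) else 0


def ld_blocks(rmap: RecombinationMap, rate_threshold: float = 0.9) -> LdBlockMap:
    """A new LD block starts after every interval with rate >= threshold."""
    if rate_threshold <= 0:
        raise ValueError("rate_threshold must be positive")
    if len(rmap.positions) == 0:
        raise ValueError("empty recombination map")
    hot = rmap.rates >= rate_threshold
    block = np.concatenate([[0], np.cumsum(hot)]).astype(int)
    bounds = [(int(rmap.positions[i]), int(rmap.positions[i + 1]))
              for i in np.flatnonzero(hot)]
    return LdBlockMap(rmap.chromosome, block, bounds)


def hotspot_intervals(rmaps: dict[str, RecombinationMap] | RecombinationMap,
                      rate_threshold: float = 0.9) -> pd.DataFrame:
    """Recombination-hotspot intervals (rate >= threshold) as a chrom/start/end frame."""
    if isinstance(rmaps, RecombinationMap):
        rmaps = {rmaps.chromosome: rmaps}
    rows = []
    for chrom, rmap in rmaps.items():
        for i in np.flatnonzero(rmap.rates >= rate_threshold):
            rows.append((chrom, int(rmap.positions[i]), int(rmap.positions[i + 1])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _best_per_block(ubf: np.ndarray, blocks: np.ndarray,
                    positions: np.ndarray) -> np.ndarray:
    """Index of the top-UBF SNP per block; ties broken by lowest coordinate."""
    best = {}
    order = np.lexsort((positions, -ubf))  # by descending UBF, then position
    for i in order:
        b = blocks[i]
        if b not in best:
            best[b] = i
    return np.array(sorted(best.values()), dtype=int)


def tier_scan(gene_row: pd.Series, traits: pd.DataFrame, genotypes: GenotypeMatrix,
              block_index: np.ndarray, prior: PriorGrid | None = None,
              max_tiers: int = 4, bf_floor: float | None = 2.0,
              gene_expression_mean: float | None = None) -> pd.DataFrame:
    """Tiered independently-associated SNPs for one gene.

    ``traits`` holds the gene's probe-cluster residual traits (columns);
    ``genotypes``/``block_index`` are restricted to the gene's cis SNPs.
    Records from all probe clusters are unioned.  ``bf_floor=None`` admits
    all tiers regardless of evidence (used to build FDR curves).
    """
    prior = prior or PriorGrid()
    floor = -np.inf if bf_floor is None else bf_floor
    G = genotypes.dosages
    poly = G.std(axis=0) > 0
    records = []
    tss = int(gene_row["tss"])
    for cluster in traits.columns:
        y = traits[cluster].to_numpy(dtype=float)
        ubf = np.full(G.shape[1], -np.inf)
        ubf[poly] = batch_univariate_log10bf(y, G[:, poly], prior)
        cand = _best_per_block(ubf, block_index, genotypes.positions)
        cand = cand[np.isfinite(ubf[cand])]
        if len(cand) == 0:
            continue
        accepted: list[int] = []
        accepted_blocks: list[int] = []
        tier_bfs: list[float] = []
        while len(accepted) < max_tiers:
            avail = [i for i in cand if block_index[i] not in accepted_blocks]
            if not avail:
                break
            if not accepted:
                scores = {i: ubf[i] for i in avail}
            else:
                Gc = G[:, accepted]
                scores = {}
                for i in avail:
                    try:
                        scores[i] = multivariate_log10bf(y, G[:, i], Gc, prior)
                    except ValueError:  # collinear with the accepted set
                        continue
                if not scores:
                    break
            best_i = min(scores, key=lambda i: (-scores[i], genotypes.positions[i]))
            if scores[best_i] < floor:
                break
            accepted.append(best_i)
            accepted_blocks.append(int(block_index[best_i]))
            tier_bfs.append(scores[best_i])
        for tier, (i, mbf) in enumerate(zip(accepted, tier_bfs), start=1):
            beta, r2, se = effect_estimate(y, G[:, i])
            records.append({
                "GENE": gene_row["gene_id"], "CLUSTER": cluster,
                "CHR": gene_row["chrom"], "STRAND": gene_row["strand"],
                "TSS": tss, "TES": int(gene_row["tes"]),
                "RSID": genotypes.snp_ids[i],
                "HS_INDEX": int(block_index[i]),
                "RSCOORD": int(genotypes.positions[i]),
                "TIER": tier, "UBF": float(ubf[i]), "MBF": float(mbf),
                "BETA": float(beta), "MAF": float(genotypes.maf[i]),
                "GEX": float(gene_expression_mean) if gene_expression_mean is not None
                       else float(np.mean(y)),
                "TSS_DIST": int(genotypes.positions[i]) - tss,
            })
    return pd.DataFrame(records, columns=RECORD_COLUMNS)


def scan_study(traits: pd.DataFrame, genotypes_by_chrom: dict[str, GenotypeMatrix],
               gene_models: pd.DataFrame,
               blocks_by_chrom: dict[str, np.ndarray],
               prior: PriorGrid | None = None, max_tiers: int = 4,
               bf_floor: float | None = None, window: int = 1_000_000,
               cluster_to_gene: pd.DataFrame | None = None,
               gene_means: pd.Series | None = None) -> pd.DataFrame:
    """Tier scan over all genes of a study.

    ``traits`` columns are probe-cluster traits; ``cluster_to_gene`` maps
    trait id -> gene id (identity when trait ids are gene ids).
    """
    gm = annotate_tss_tes(gene_models) if "tss" not in gene_models else gene_models
    if cluster_to_gene is None:
        cluster_to_gene = pd.DataFrame({"cluster_id": traits.columns,
                                        "gene_id": [c.split(".c")[0]
                                                    for c in traits.columns]})
    by_gene = dict(tuple(cluster_to_gene.groupby("gene_id")))
    frames = []
    for _, gene in gm.iterrows():
        grp = by_gene.get(gene["gene_id"])
        if grp is None:
            continue
        clusters = [c for c in grp["cluster_id"] if c in traits.columns]
        if not clusters:
            continue
        gt = genotypes_by_chrom[gene["chrom"]]
        lo, hi = cis_bounds(gene, window)
        cis = np.flatnonzero((gt.positions >= lo) & (gt.positions <= hi))
        if len(cis) == 0:
            continue
        sub = gt.subset_snps(cis)
        blocks = blocks_by_chrom[gene["chrom"]][cis]
        mean = float(gene_means[gene["gene_id"]]) if gene_means is not None else None
        frames.append(tier_scan(gene, traits[clusters], sub, blocks, prior,
                                max_tiers=max_tiers, bf_floor=bf_floor,
                                gene_expression_mean=mean))
    if not frames:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def _ols_rss(y: np.ndarray, X: np.ndarray | None) -> tuple[float, int]:
    n = len(y)
    if X is None or X.shape[1] == 0:
        return float(np.sum((y - y.mean()) ** 2)), 1
    A = np.column_stack([np.ones(n), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    rss = float(np.sum((y - A @ coef) ** 2))
    return rss, A.shape[1]


def _snp_design(G: np.ndarray, cols: list[int]) -> np.ndarray:
    from .bayes import dominance_encoding
    sub = G[:, cols]
    return np.hstack([sub, dominance_encoding(sub)])


def forward_stepwise_bic(y: np.ndarray, cis_genotypes: np.ndarray) -> list[int]:
    """Greedy forward SNP selection by BIC improvement; stops at no improvement.

    Each SNP contributes the additive + dominance covariates of the
    association model (two parameters), so the BIC penalty is 2 log n per
    SNP.  Returns the ordered list of selected column indices (possibly
    empty).
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(cis_genotypes, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    if G.shape[1] < 1:
        raise ValueError("need at least one cis SNP")
    n = len(y)
    tss = float(np.sum((y - y.mean()) ** 2))
    selected: list[int] = []
    rss0, k0 = _ols_rss(y, None)
    current = n * np.log(max(rss0, np.finfo(float).tiny) / n) + k0 * np.log(n)
    poly = np.flatnonzero(G.std(axis=0) > 0)
    while True:
        if rss0 <= 1e-12 * max(tss, 1.0):
            return selected  # numerically perfect fit
        best_j, best_bic, best_rss = None, current, rss0
        for j in poly:
            if j in selected:
                continue
            rss, k = _ols_rss(y, _snp_design(G, selected + [j]))
            bic = n * np.log(max(rss, np.finfo(float).tiny) / n) + k * np.log(n)
            if bic < best_bic - 1e-10:
                best_bic, best_j, best_rss = bic, j, rss
        if best_j is None:
            return selected
        selected.append(int(best_j))
        current, rss0 = best_bic, best_rss


@dataclass
class FdrTable:
    """Per-tier cutoff table: observed and permuted counts, monotone FDR."""

    table: pd.DataFrame  # columns tier, cutoff, n_obs, n_perm, fdr
    n_perm_runs: int

    def cutoff_at(self, target_fdr: float, tier: int = 1) -> float | None:
        """Smallest cutoff whose monotonized FDR estimate is <= target."""
        sub = self.table[self.table["tier"] == tier]
        ok = sub[(sub["fdr"] <= target_fdr) & (sub["n_obs"] > 0)]
        if len(ok) == 0:
            return None
        return float(ok["cutoff"].min())


def _tier_counts(records: pd.DataFrame, cutoffs: np.ndarray, tier: int) -> np.ndarray:
    vals = records.loc[records["TIER"] == tier, "MBF"].to_numpy()
    return np.array([(vals >= c).sum() for c in cutoffs], dtype=float)


def permutation_fdr(traits: pd.DataFrame, genotypes_by_chrom: dict,
                    gene_models: pd.DataFrame, blocks_by_chrom: dict,
                    prior: PriorGrid | None = None, seed: int = 0,
                    n_perm: int = 1, max_tiers: int = 4,
                    cutoffs: np.ndarray | None = None,
                    window: int = 1_000_000,
                    cluster_to_gene: pd.DataFrame | None = None,
                    observed_records: pd.DataFrame | None = None
                    ) -> tuple[FdrTable, pd.DataFrame]:
    """Permutation FDR table from one (or more) shared sample permutations.

    The same sample permutation is applied to every expression trait, the
    full tier scan re-run, and per tier FDR(c) = min(1, N_perm(c)/N_obs(c)),
    monotonized to be non-increasing in the cutoff.  Returns the table and
    the observed (unpermuted) records.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    if observed_records is None:
        observed_records = scan_study(traits, genotypes_by_chrom, gene_models,
                                      blocks_by_chrom, prior, max_tiers=max_tiers,
                                      bf_floor=None, window=window,
                                      cluster_to_gene=cluster_to_gene)
    perm_frames = []
    for _ in range(n_perm):
        perm = rng.permutation(len(traits))
        perm_traits = pd.DataFrame(traits.to_numpy()[perm], index=traits.index,
                                   columns=traits.columns)
        perm_frames.append(scan_study(perm_traits, genotypes_by_chrom, gene_models,
                                      blocks_by_chrom, prior, max_tiers=max_tiers,
                                      bf_floor=None, window=window,
                                      cluster_to_gene=cluster_to_gene))
    if cutoffs is None:
        top = max(observed_records["MBF"].max() if len(observed_records) else 1.0, 1.0)
        cutoffs = np.arange(0.0, np.ceil(top) + 0.25, 0.25)
    rows = []
    for tier in range(1, max_tiers + 1):
        n_obs = _tier_counts(observed_records, cutoffs, tier)
        n_perm_counts = np.mean(
            [_tier_counts(f, cutoffs, tier) for f in perm_frames], axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            fdr = np.where(n_obs > 0, np.minimum(1.0, n_perm_counts / n_obs), 1.0)
        fdr = np.minimum.accumulate(fdr)  # non-increasing in cutoff
        fdr[n_obs == 0] = 1.0  # undefined without observed associations
        for c, no, npp, f in zip(cutoffs, n_obs, n_perm_counts, fdr):
            rows.append((tier, float(c), int(no), float(npp), float(f)))
    table = pd.DataFrame(rows, columns=["tier", "cutoff", "n_obs", "n_perm", "fdr"])
    return FdrTable(table, n_perm), observed_records
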