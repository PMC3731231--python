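"""Synthetic genotype / expression / CRE data with a machine-readable planted truth.

The generator emulates the statistical structure a cis-eQTL + cis-regulatory
element analysis assumes:

* genotypes with recombination-hotspot-delimited LD blocks (a
  block-exchangeable haplotype copying model, not a coalescent),
* expression traits carrying tiered planted cis-eQTLs, shared latent
  confounders and Gaussian noise,
* two "cell types" whose shared/specific eQTLs follow the five bivariate
  model classes (stable, A-not-B, B-not-A, A-and-B, A-opposite-B),
* activating / repressive / insulator interval tracks that are partly
  cell-type specific and enriched (or depleted) around planted causal SNPs.

All outputs are deterministic given the seed, and every planted-truth row is
recomputable from the emitted tables alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BIVARIATE_CLASSES = ("stable", "A-not-B", "B-not-A", "A-and-B", "A-opposite-B")

__all__ = [
    "RecombinationMap",
    "GenotypeMatrix",
    "CreTrack",
    "simulate_recomb_map",
    "simulate_genotypes",
    "make_gene_models",
    "random_eqtl_plan",
    "simulate_expression",
    "as_intensities",
    "simulate_cre_tracks",
    "simulate_gwas_snps",
    "simulate_study_set",
    "StudySet",
    "BIVARIATE_CLASSES",
]


@dataclass
class RecombinationMap:
    """Per-chromosome SNP positions and cM/Mb rates per inter-SNP interval."""

    chromosome: str
    positions: np.ndarray  # bp, strictly increasing
    rates: np.ndarray      # cM/Mb, length = len(positions) - 1

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")
        if len(self.rates) != len(self.positions) - 1:
            raise ValueError("need exactly one rate per inter-SNP interval")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chromosome,
            "pos": self.positions,
            "rate_to_next": np.append(self.rates, np.nan),
        })


@dataclass
class GenotypeMatrix:
    """Samples x SNPs mean dosages oriented to the minor allele."""

    sample_ids: list[str]
    snp_ids: list[str]
    chromosomes: np.ndarray
    positions: np.ndarray
    major: np.ndarray
    minor: np.ndarray
    dosages: np.ndarray  # (n_samples, n_snps), values in [0, 2]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        ok = np.isnan(self.dosages) | ((self.dosages >= 0) & (self.dosages <= 2))
        if not np.all(ok):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def maf(self) -> np.ndarray:
        freq = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def snp_map(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_id": self.snp_ids,
            "chrom": self.chromosomes,
            "pos": self.positions,
            "major": self.major,
            "minor": self.minor,
        })

    def subset_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            sample_ids=self.sample_ids,
            snp_ids=[self.snp_ids[i] for i in idx],
            chromosomes=self.chromosomes[idx],
            positions=self.positions[idx],
            major=self.major[idx],
            minor=self.minor[idx],
            dosages=self.dosages[:, idx],
        )

    def subset_samples(self, rows: np.ndarray) -> "GenotypeMatrix":
        rows = np.asarray(rows)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in rows],
            snp_ids=self.snp_ids,
            chromosomes=self.chromosomes,
            positions=self.positions,
            major=self.major,
            minor=self.minor,
            dosages=self.dosages[rows],
        )


@dataclass
class CreTrack:
    """A named, cell-type-labeled interval set (0-based, half-open)."""

    track_id: str
    cell_type: str
    cre_class: str  # activating | repressive | insulator
    intervals: pd.DataFrame  # columns chrom, start, end
    merged: bool = False

    def __post_init__(self) -> None:
        iv = self.intervals
        if len(iv) and np.any(iv["start"].to_numpy() >= iv["end"].to_numpy()):
            raise ValueError("intervals must satisfy start < end")
        self.intervals = iv.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


def simulate_recomb_map(n_snps: int, spacing: int = 2000, hotspot_every: int = 10,
                        hotspot_rate: float = 2.0, background_rate: float = 0.1,
                        chromosome: str = "chr1", start: int = 1_000_000,
                        seed: int | None = None) -> RecombinationMap:
    """Evenly spaced SNPs with a recombination hotspot every ``hotspot_every``-th interval.

    Deterministic; ``seed`` is accepted for interface uniformity but unused.
    """
    if n_snps < 2:
        raise ValueError("need at least 2 SNPs")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if background_rate < 0 or hotspot_rate < background_rate:
        raise ValueError("require 0 <= background_rate <= hotspot_rate")
    positions = start + spacing * np.arange(n_snps, dtype=np.int64)
    rates = np.full(n_snps - 1, background_rate)
    # interval i sits between SNPs i and i+1; 1-based interval count
    hot = (np.arange(1, n_snps) % hotspot_every) == 0
    rates[hot] = hotspot_rate
    return RecombinationMap(chromosome, positions, rates)


def _blocks_from_rates(rates: np.ndarray, rate_threshold: float) -> np.ndarray:
    """Block index per SNP: a new block starts after each interval with rate >= threshold."""
    return np.concatenate([[0], np.cumsum(rates >= rate_threshold)]).astype(int)


def simulate_genotypes(n_samples: int, rmap: RecombinationMap,
                       maf_range: tuple[float, float] = (0.05, 0.5),
                       within_block_r2: float = 0.8, seed: int = 0,
                       rate_threshold: float = 0.9,
                       snp_prefix: str | None = None,
                       max_retries: int = 50) -> GenotypeMatrix:
    """Draw LD-blocked genotypes by block-exchangeable haplotype copying.

    Within a block every haplotype carries a backbone uniform; each SNP copies
    it with probability ``sqrt(within_block_r2)`` and otherwise draws fresh,
    giving pairwise dosage correlation ~= within_block_r2 at equal MAFs and
    exact independence across blocks.  Monomorphic draws are resampled a
    bounded number of times.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
    if not (0 <= within_block_r2 <= 1):
        raise ValueError("within_block_r2 must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    m = len(rmap.positions)
    n_hap = 2 * n_samples
    block = _blocks_from_rates(rmap.rates, rate_threshold)
    mafs = rng.uniform(lo, hi, size=m)
    copy_prob = np.sqrt(within_block_r2)

    H = np.empty((n_hap, m), dtype=np.int8)
    for b in np.unique(block):
        cols = np.flatnonzero(block == b)
        backbone = rng.random((n_hap, 1))
        use_backbone = rng.random((n_hap, len(cols))) < copy_prob
        fresh = rng.random((n_hap, len(cols)))
        u = np.where(use_backbone, backbone, fresh)
        H[:, cols] = (u < mafs[cols]).astype(np.int8)

    dos = (H[0::2] + H[1::2]).astype(float)
    for _ in range(max_retries):
        mono = np.flatnonzero(dos.std(axis=0) == 0)
        if len(mono) == 0:
            break
        redraw = (rng.random((n_hap, len(mono))) < mafs[mono]).astype(np.int8)
        dos[:, mono] = (redraw[0::2] + redraw[1::2]).astype(float)
    else:
        raise RuntimeError("monomorphic SNPs persisted after bounded resampling")

    # orient to the minor allele
    freq = dos.mean(axis=0) / 2.0
    flip = freq > 0.5
    dos[:, flip] = 2.0 - dos[:, flip]
    letters = np.array(list("ACGT"))
    pair = rng.integers(0, 4, size=(m, 2))
    pair[:, 1] = (pair[:, 0] + 1 + rng.integers(0, 3, size=m)) % 4
    major, minor = letters[pair[:, 0]], letters[pair[:, 1]]
    major = major.copy()
    minor = minor.copy()
    major[flip], minor[flip] = minor[flip], major[flip]

    prefix = snp_prefix or rmap.chromosome
    snp_ids = [f"{prefix}_s{i:04d}" for i in range(m)]
    sample_ids = [f"ind{i:04d}" for i in range(n_samples)]
    return GenotypeMatrix(sample_ids, snp_ids, np.full(m, rmap.chromosome, dtype=object),
                          rmap.positions.copy(), major, minor, dos)


def make_gene_models(chromosomes: list[str], tss_positions: list[int],
                     gene_length: int = 20_000, strand: str = "+") -> pd.DataFrame:
    """One gene model per entry; TSS at ``start`` on '+', at ``end`` on '-'."""
    rows = []
    for i, (chrom, tss) in enumerate(zip(chromosomes, tss_positions)):
        if strand == "+":
            start, end = tss, tss + gene_length
        else:
            start, end = tss - gene_length, tss
        rows.append({"gene_id": f"g{i:04d}", "chrom": chrom, "strand": strand,
                     "start": start, "end": end})
    gm = pd.DataFrame(rows)
    return annotate_tss_tes(gm)


def annotate_tss_tes(gene_models: pd.DataFrame) -> pd.DataFrame:
    gm = gene_models.copy()
    plus = gm["strand"] == "+"
    gm["tss"] = np.where(plus, gm["start"], gm["end"])
    gm["tes"] = np.where(plus, gm["end"], gm["start"])
    return gm


def cis_bounds(gene_row, window: int = 1_000_000) -> tuple[int, int]:
    lo = min(gene_row["tss"], gene_row["tes"]) - window
    hi = max(gene_row["tss"], gene_row["tes"]) + window
    return int(lo), int(hi)


def random_eqtl_plan(gene_models: pd.DataFrame,
                     genotypes_by_chrom: dict[str, GenotypeMatrix],
                     blocks_by_chrom: dict[str, np.ndarray],
                     eqtl_fraction: float = 0.5,
                     two_tier_fraction: float = 0.25,
                     beta: float = 0.7,
                     effect_r2: float | None = None,
                     class_mix: dict[str, float] | None = None,
                     seed: int = 0) -> pd.DataFrame:
    """Draw a planted-eQTL plan: which genes get causal SNPs, in which blocks.

    Tier-1 and tier-2 causal SNPs are placed in distinct LD blocks.  Each
    eQTL gene is assigned one of the five bivariate classes; with the default
    mix most planted eQTLs are stable across the two cell types.  Effects
    are either a fixed per-dosage ``beta`` (trait-SD units) or, when
    ``effect_r2`` is given, a per-SNP magnitude chosen at simulation time so
    the planted SNP explains that fraction of the trait variance.
    """
    rng = np.random.default_rng(seed)
    mix = class_mix or {"stable": 0.6, "A-not-B": 0.2, "B-not-A": 0.1,
                        "A-and-B": 0.05, "A-opposite-B": 0.05}
    classes = list(mix)
    probs = np.array([mix[c] for c in classes], dtype=float)
    probs /= probs.sum()
    rows = []
    for _, gene in gene_models.iterrows():
        if rng.random() >= eqtl_fraction:
            continue
        gt = genotypes_by_chrom[gene["chrom"]]
        block = blocks_by_chrom[gene["chrom"]]
        lo, hi = cis_bounds(gene)
        cis = np.flatnonzero((gt.positions >= lo) & (gt.positions <= hi))
        if len(cis) == 0:
            continue
        bv_class = classes[rng.choice(len(classes), p=probs)]
        n_tiers = 2 if (rng.random() < two_tier_fraction
                        and len(np.unique(block[cis])) >= 2) else 1
        chosen_blocks: list[int] = []
        for tier in range(1, n_tiers + 1):
            avail = cis[~np.isin(block[cis], chosen_blocks)]
            if len(avail) == 0:
                break
            snp_idx = int(rng.choice(avail))
            chosen_blocks.append(int(block[snp_idx]))
            sign = float(rng.choice([-1.0, 1.0]))
            rows.append({
                "gene_id": gene["gene_id"],
                "snp_id": gt.snp_ids[snp_idx],
                "chrom": gene["chrom"],
                "pos": int(gt.positions[snp_idx]),
                "tier": tier,
                "beta": sign if effect_r2 is not None else float(beta * sign),
                "target_r2": effect_r2 if effect_r2 is not None else np.nan,
                "bivariate_class": bv_class,
            })
    return pd.DataFrame(rows, columns=["gene_id", "snp_id", "chrom", "pos",
                                       "tier", "beta", "target_r2",
                                       "bivariate_class"])


def _betas_for_class(beta: float, bv_class: str,
                     a_and_b_ratio: float = 0.5) -> tuple[float, float]:
    if bv_class == "stable":
        return beta, beta
    if bv_class == "A-not-B":
        return beta, 0.0
    if bv_class == "B-not-A":
        return 0.0, beta
    if bv_class == "A-and-B":
        return beta, beta * a_and_b_ratio
    if bv_class == "A-opposite-B":
        return beta, -beta
    raise ValueError(f"unknown bivariate class {bv_class!r}")


def simulate_expression(genotypes_by_celltype: dict[str, GenotypeMatrix] |
                        dict[str, dict[str, GenotypeMatrix]],
                        gene_models: pd.DataFrame,
                        eqtl_plan: pd.DataFrame,
                        n_confounders: int = 3,
                        confounder_var_frac: float = 0.3,
                        noise_sd: float = 1.0,
                        seed: int = 0,
                        return_confounders: bool = False):
    """Realize expression traits from the plan, for each cell type.

    ``genotypes_by_celltype`` maps cell type -> GenotypeMatrix (single
    chromosome) or cell type -> {chrom: GenotypeMatrix}.  The first key is
    cell type "A" for the bivariate class semantics; the second "B".  Returns
    (expression per cell type, planted-truth table with realized per-cell
    effects).

    trait = sum_t beta_t * dosage_t + confounder loadings + N(0, noise_sd^2);
    loadings are scaled so confounders contribute ``confounder_var_frac`` of
    the non-genetic variance.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if not (0 <= confounder_var_frac < 1):
        raise ValueError("confounder_var_frac must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    celltypes = list(genotypes_by_celltype)
    gene_models = annotate_tss_tes(gene_models) if "tss" not in gene_models else gene_models

    def _gt_for(ct: str, chrom: str) -> GenotypeMatrix:
        entry = genotypes_by_celltype[ct]
        if isinstance(entry, dict):
            return entry[chrom]
        return entry

    # validate cis placement
    gm_idx = gene_models.set_index("gene_id")
    for _, row in eqtl_plan.iterrows():
        gene = gm_idx.loc[row["gene_id"]]
        lo, hi = cis_bounds(gene)
        if not (lo <= row["pos"] <= hi):
            raise ValueError(
                f"planted SNP {row['snp_id']} outside cis window of {row['gene_id']}")

    truth_rows = []
    expr: dict[str, pd.DataFrame] = {}
    plan_by_gene = dict(tuple(eqtl_plan.groupby("gene_id"))) if len(eqtl_plan) else {}

    # realized per-cell-type betas, shared across cell types via the class rule
    has_conf = n_confounders > 0 and confounder_var_frac > 0
    sigma_ng2 = noise_sd ** 2 / (1 - confounder_var_frac) if has_conf \
        else noise_sd ** 2
    beta_ab: dict[tuple[str, str], tuple[float, float]] = {}
    for _, row in eqtl_plan.iterrows():
        mag = float(row["beta"])
        target_r2 = float(row.get("target_r2", np.nan)) \
            if "target_r2" in eqtl_plan.columns else np.nan
        if np.isfinite(target_r2) and target_r2 > 0:
            gt_a = _gt_for(celltypes[0], row["chrom"])
            v = float(gt_a.dosages[:, gt_a.snp_ids.index(row["snp_id"])].var())
            mag = float(np.sign(mag)) * np.sqrt(
                target_r2 / (1.0 - target_r2) * sigma_ng2 / v)
        beta_ab[(row["gene_id"], row["snp_id"])] = _betas_for_class(
            mag, row["bivariate_class"])

    confounders: dict[str, np.ndarray] = {}
    for ct_i, ct in enumerate(celltypes):
        first = _gt_for(ct, gene_models["chrom"].iloc[0])
        n = first.n_samples
        U = rng.standard_normal((n, n_confounders)) if n_confounders else None
        if U is not None:
            confounders[ct] = U
        cols = {}
        for _, gene in gene_models.iterrows():
            gt = _gt_for(ct, gene["chrom"])
            y = rng.normal(0.0, noise_sd, size=gt.n_samples)
            if U is not None and confounder_var_frac > 0:
                lam = rng.standard_normal(n_confounders)
                lam *= np.sqrt(confounder_var_frac / (1 - confounder_var_frac)) \
                    * noise_sd / np.linalg.norm(lam)
                y = y + U @ lam
            for _, prow in plan_by_gene.get(gene["gene_id"], pd.DataFrame()).iterrows():
                b_a, b_b = beta_ab[(prow["gene_id"], prow["snp_id"])]
                b = b_a if ct_i == 0 else b_b
                if b != 0.0:
                    j = gt.snp_ids.index(prow["snp_id"])
                    y = y + b * gt.dosages[:, j]
            cols[gene["gene_id"]] = y
        expr[ct] = pd.DataFrame(cols, index=first.sample_ids)

    ct_a = celltypes[0]
    ct_b = celltypes[1] if len(celltypes) > 1 else None
    for _, row in eqtl_plan.iterrows():
        b_a, b_b = beta_ab[(row["gene_id"], row["snp_id"])]
        affected = [ct for ct, b in zip([ct_a, ct_b], [b_a, b_b])
                    if ct is not None and b != 0.0]
        truth_rows.append({
            "gene_id": row["gene_id"], "snp_id": row["snp_id"],
            "chrom": row["chrom"], "pos": row["pos"], "tier": row["tier"],
            "beta_a": b_a, "beta_b": b_b,
            "cell_types": ",".join(affected),
            "bivariate_class": row["bivariate_class"],
        })
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "snp_id", "chrom", "pos",
                                              "tier", "beta_a", "beta_b",
                                              "cell_types", "bivariate_class"])
    if return_confounders:
        return expr, truth, confounders
    return expr, truth


def as_intensities(expr: pd.DataFrame, base: float = 8.0,
                   missing_fraction: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Map Gaussian traits to array-like intensities (2**(y+base)), with optional missingness."""
    rng = np.random.default_rng(seed)
    vals = np.power(2.0, expr.to_numpy() + base)
    if missing_fraction > 0:
        mask = rng.random(vals.shape) < missing_fraction
        vals = np.where(mask, np.nan, vals)
    return pd.DataFrame(vals, index=expr.index, columns=expr.columns)


def _draw_intervals(rng: np.random.Generator, chroms: np.ndarray,
                    centers: np.ndarray, width_range: tuple[int, int]) -> pd.DataFrame:
    widths = rng.integers(width_range[0], width_range[1] + 1, size=len(centers))
    starts = centers - widths // 2
    return pd.DataFrame({"chrom": chroms, "start": starts, "end": starts + widths})


def simulate_cre_tracks(gene_models: pd.DataFrame, snp_map: pd.DataFrame,
                        truth: pd.DataFrame, celltypes: list[str],
                        classes: tuple[str, ...] = ("activating", "repressive", "insulator"),
                        specific_fraction: float = 0.3,
                        eqtl_enrichment: float = 3.0,
                        background_rate: float = 0.15,
                        width_range: tuple[int, int] = (200, 600),
                        insulators_per_chrom: int = 4,
                        seed: int = 0) -> dict[str, CreTrack]:
    """Place CRE interval tracks per class and cell type.

    Non-causal SNP positions seed background intervals at ``background_rate``;
    causal SNPs of the matched cell type are covered by activating intervals
    at ``eqtl_enrichment``-fold that rate and by repressive intervals at
    1/``eqtl_enrichment``-fold (depletion).  A ``specific_fraction`` of
    intervals exist in exactly one cell type; the rest are shared by all.
    Insulator (CTCF-like) intervals are placed independently of SNPs.
    """
    if len(gene_models) == 0:
        raise ValueError("empty gene set")
    if not (0 <= specific_fraction <= 1):
        raise ValueError("specific_fraction must lie in [0, 1]")
    if eqtl_enrichment < 1:
        raise ValueError("eqtl_enrichment must be >= 1")
    rng = np.random.default_rng(seed)

    causal_by_ct: dict[str, set[str]] = {ct: set() for ct in celltypes}
    if len(truth):
        for _, row in truth.iterrows():
            for ct in str(row["cell_types"]).split(","):
                if ct in causal_by_ct:
                    causal_by_ct[ct].add(row["snp_id"])
    all_causal = set().union(*causal_by_ct.values()) if causal_by_ct else set()

    snp_ids = snp_map["snp_id"].to_numpy()
    chroms = snp_map["chrom"].to_numpy()
    pos = snp_map["pos"].to_numpy()
    is_causal = np.isin(snp_ids, sorted(all_causal))

    tracks: dict[str, CreTrack] = {}
    for cls in classes:
        if cls == "insulator":
            per_ct: dict[str, list[pd.DataFrame]] = {ct: [] for ct in celltypes}
            for chrom in gene_models["chrom"].unique():
                on = pos[chroms == chrom]
                span = (int(on.min()) - 50_000, int(on.max()) + 50_000)
                centers = rng.integers(span[0], span[1], size=insulators_per_chrom)
                iv = _draw_intervals(rng, np.full(len(centers), chrom, dtype=object),
                                     centers, width_range)
                specific = rng.random(len(iv)) < specific_fraction
                owner = rng.integers(0, len(celltypes), size=len(iv))
                for k, ct in enumerate(celltypes):
                    keep = (~specific) | (owner == k)
                    per_ct[ct].append(iv[keep])
            for ct in celltypes:
                iv = pd.concat(per_ct[ct], ignore_index=True)
                tracks[f"{cls}_{ct}"] = CreTrack(f"{cls}_{ct}", ct, cls, iv)
            continue

        # SNP-seeded activating / repressive intervals
        per_ct_frames: dict[str, list[pd.DataFrame]] = {ct: [] for ct in celltypes}
        bg_idx = np.flatnonzero(~is_causal)
        covered_bg = bg_idx[rng.random(len(bg_idx)) < background_rate]
        iv_bg = _draw_intervals(rng, chroms[covered_bg],
                                pos[covered_bg].astype(np.int64), width_range)
        specific = rng.random(len(iv_bg)) < specific_fraction
        owner = rng.integers(0, len(celltypes), size=len(iv_bg))
        for k, ct in enumerate(celltypes):
            keep = (~specific) | (owner == k)
            per_ct_frames[ct].append(iv_bg[keep])

        # one coverage draw per causal SNP; a covered interval exists in all
        # of the SNP's matched cell types, and leaks into unmatched cell
        # types only when it is not cell-type specific
        if cls == "activating":
            rate = min(1.0, eqtl_enrichment * background_rate)
        else:  # repressive: depleted at causal SNPs
            rate = background_rate / eqtl_enrichment
        causal_idx = np.flatnonzero(is_causal)
        covered = causal_idx[rng.random(len(causal_idx)) < rate]
        iv = _draw_intervals(rng, chroms[covered],
                             pos[covered].astype(np.int64), width_range)
        sp = rng.random(len(iv)) < specific_fraction
        matched = np.array(
            [[snp_ids[i] in causal_by_ct[ct] for ct in celltypes]
             for i in covered], dtype=bool).reshape(len(covered), len(celltypes))
        for k2, ct2 in enumerate(celltypes):
            keep = matched[:, k2] | (~sp)
            per_ct_frames[ct2].append(iv[keep])

        for ct in celltypes:
            iv = pd.concat(per_ct_frames[ct], ignore_index=True)
            tracks[f"{cls}_{ct}"] = CreTrack(f"{cls}_{ct}", ct, cls, iv)
    return tracks


def annotate_truth_cre(truth: pd.DataFrame, tracks: dict[str, CreTrack],
                       pad: int = 500) -> pd.DataFrame:
    """Add per-track CRE membership flags to the truth table (recomputable from files)."""
    from .overlap import snp_overlaps
    out = truth.copy()
    snps = out[["chrom", "pos"]]
    for tid, track in tracks.items():
        out[f"in_{tid}"] = snp_overlaps(snps, track, pad=pad)
    return out


def simulate_gwas_snps(snp_map: pd.DataFrame, tracks: dict[str, CreTrack],
                       celltype: str, n_snps: int = 200,
                       in_cre_fraction: float = 0.7, seed: int = 0) -> pd.DataFrame:
    """A synthetic GWAS SNP list enriched inside the given cell type's activating CREs."""
    from .overlap import snp_overlaps
    rng = np.random.default_rng(seed)
    track = tracks[f"activating_{celltype}"]
    inside = snp_overlaps(snp_map[["chrom", "pos"]], track, pad=0)
    in_idx = np.flatnonzero(inside)
    out_idx = np.flatnonzero(~inside)
    n_in = min(len(in_idx), int(round(n_snps * in_cre_fraction)))
    n_out = min(len(out_idx), n_snps - n_in)
    chosen = np.concatenate([
        rng.choice(in_idx, size=n_in, replace=False),
        rng.choice(out_idx, size=n_out, replace=False),
    ])
    chosen.sort()
    return snp_map.iloc[chosen][["snp_id", "chrom", "pos"]].reset_index(drop=True)


@dataclass
class StudySet:
    """A complete synthetic study collection with planted truth.

    ``studies`` maps study id -> (cell_type, GenotypeMatrix dict by chrom,
    raw-intensity expression).  "A_discovery" and "B_paired" share
    individuals (same donors, two tissues); "A_replication" is independent.
    """

    rmaps: dict[str, RecombinationMap]
    gene_models: pd.DataFrame
    genotypes: dict[str, dict[str, GenotypeMatrix]]  # study -> chrom -> gt
    celltype_of: dict[str, str]
    expression: dict[str, pd.DataFrame]   # study -> samples x genes (intensities)
    traits_true: dict[str, pd.DataFrame]  # study -> samples x genes (latent)
    plan: pd.DataFrame
    truth: pd.DataFrame
    tracks: dict[str, CreTrack]
    gwas: pd.DataFrame
    seed: int

    def snp_map(self) -> pd.DataFrame:
        frames = [gt.snp_map() for gt in self.genotypes["A_discovery"].values()]
        return pd.concat(frames, ignore_index=True)


def simulate_study_set(n_genes: int = 200, n_snps_per_gene: int = 50,
                       n_samples: int = 200, n_samples_replication: int | None = None,
                       snp_spacing: int = 2000, hotspot_every: int = 10,
                       hotspot_rate: float = 2.0, background_rate: float = 0.1,
                       maf_range: tuple[float, float] = (0.05, 0.5),
                       within_block_r2: float = 0.8,
                       eqtl_fraction: float = 0.5, two_tier_fraction: float = 0.25,
                       beta: float = 0.7, effect_r2: float | None = 0.15,
                       class_mix: dict[str, float] | None = None,
                       n_confounders: int = 3, confounder_var_frac: float = 0.3,
                       noise_sd: float = 1.0, specific_fraction: float = 0.3,
                       eqtl_enrichment: float = 3.0, cre_background_rate: float = 0.15,
                       missing_fraction: float = 0.02, n_gwas: int = 200,
                       seed: int = 0) -> StudySet:
    """End-to-end synthetic study collection: the package's default test bed.

    Three studies over two cell types: "A_discovery" and "A_replication"
    (independent samples, cell type A) and "B_paired" (cell type B, same
    donors as A_discovery).  One gene per chromosome with
    ``n_snps_per_gene`` cis SNPs.
    """
    rng = np.random.default_rng(seed)
    n_rep = n_samples_replication or n_samples
    celltypes = ["A", "B"]

    rmaps: dict[str, RecombinationMap] = {}
    pool: dict[str, GenotypeMatrix] = {}
    chrom_names, tss_positions = [], []
    for gidx in range(n_genes):
        chrom = f"chr{gidx + 1}"
        rmap = simulate_recomb_map(n_snps_per_gene, spacing=snp_spacing,
                                   hotspot_every=hotspot_every,
                                   hotspot_rate=hotspot_rate,
                                   background_rate=background_rate,
                                   chromosome=chrom)
        rmaps[chrom] = rmap
        pool[chrom] = simulate_genotypes(
            n_samples + n_rep, rmap, maf_range=maf_range,
            within_block_r2=within_block_r2,
            seed=int(rng.integers(0, 2**31 - 1)))
        chrom_names.append(chrom)
        mid = int(rmap.positions[len(rmap.positions) // 2])
        tss_positions.append(mid)

    gene_models = make_gene_models(chrom_names, tss_positions)

    disc_rows = np.arange(n_samples)
    rep_rows = np.arange(n_samples, n_samples + n_rep)
    gt_disc = {c: g.subset_samples(disc_rows) for c, g in pool.items()}
    gt_rep = {c: g.subset_samples(rep_rows) for c, g in pool.items()}
    # distinct sample ids for the independent replication cohort
    for g in gt_rep.values():
        g.sample_ids = [f"rep{int(s[3:]):04d}" for s in g.sample_ids]

    blocks = {c: _blocks_from_rates(r.rates, 0.9) for c, r in rmaps.items()}
    plan = random_eqtl_plan(gene_models, gt_disc, blocks,
                            eqtl_fraction=eqtl_fraction,
                            two_tier_fraction=two_tier_fraction, beta=beta,
                            effect_r2=effect_r2, class_mix=class_mix,
                            seed=int(rng.integers(0, 2**31 - 1)))

    expr_ab, truth = simulate_expression(
        {"A": gt_disc, "B": gt_disc}, gene_models, plan,
        n_confounders=n_confounders, confounder_var_frac=confounder_var_frac,
        noise_sd=noise_sd, seed=int(rng.integers(0, 2**31 - 1)))
    expr_rep, _ = simulate_expression(
        {"A": gt_rep, "B": gt_rep}, gene_models, plan,
        n_confounders=n_confounders, confounder_var_frac=confounder_var_frac,
        noise_sd=noise_sd, seed=int(rng.integers(0, 2**31 - 1)))

    traits_true = {"A_discovery": expr_ab["A"], "A_replication": expr_rep["A"],
                   "B_paired": expr_ab["B"]}
    expression = {
        sid: as_intensities(tr, missing_fraction=missing_fraction,
                            seed=int(rng.integers(0, 2**31 - 1)))
        for sid, tr in traits_true.items()
    }

    snp_map = pd.concat([g.snp_map() for g in gt_disc.values()], ignore_index=True)
    tracks = simulate_cre_tracks(gene_models, snp_map, truth, celltypes,
                                 specific_fraction=specific_fraction,
                                 eqtl_enrichment=eqtl_enrichment,
                                 background_rate=cre_background_rate,
                                 seed=int(rng.integers(0, 2**31 - 1)))
    truth = annotate_truth_cre(truth, tracks)
    gwas = simulate_gwas_snps(snp_map, tracks, "B", n_snps=n_gwas,
                              seed=int(rng.integers(0, 2**31 - 1)))

    return StudySet(
        rmaps=rmaps, gene_models=gene_models,
        genotypes={"A_discovery": gt_disc, "A_replication": gt_rep,
                   "B_paired": gt_disc},
        celltype_of={"A_discovery": "A", "A_replication": "A", "B_paired": "B"},
        expression=expression, traits_true=traits_true,
        plan=plan, truth=truth, tracks=tracks, gwas=gwas, seed=seed)
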