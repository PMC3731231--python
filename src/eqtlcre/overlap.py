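"""Interval machinery: CRE tracks, padded SNP overlap, intervening insulators,
background SNP sets and tier-1/tier-2 SNP pairs.

Conventions: all coordinates are 0-based, half-open (BED native); SNPs are
points at their 0-based position.  A SNP overlaps a padded element iff its
position lies in ``[start - pad, end + pad)``.  A CTCF-like insulator
intervenes between a SNP and a TSS iff its midpoint ``floor((start+end)/2)``
lies strictly between the two coordinates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import CreTrack, annotate_tss_tes, cis_bounds

__all__ = [
    "merge_intervals",
    "merge_replicates",
    "snp_overlaps",
    "intervening_insulator",
    "background_snps",
    "build_snp_pairs",
    "annotate_snps",
]


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals per chromosome; adjacent half-open intervals merge."""
    if len(intervals) == 0:
        return intervals.copy()
    if np.any(intervals["start"].to_numpy() >= intervals["end"].to_numpy()):
        raise ValueError("malformed interval: start >= end")
    out = []
    for chrom, grp in intervals.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"])
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:  # overlap or half-open adjacency
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def merge_replicates(tracks: list[CreTrack]) -> CreTrack:
    """Union replicate peak calls that share a track id into one track."""
    if len(tracks) == 0:
        raise ValueError("no tracks to merge")
    tid = tracks[0].track_id
    if any(t.track_id != tid for t in tracks):
        raise ValueError("merge_replicates requires a shared track_id")
    iv = merge_intervals(pd.concat([t.intervals for t in tracks], ignore_index=True))
    return CreTrack(tid, tracks[0].cell_type, tracks[0].cre_class, iv, merged=True)


def _merged_per_chrom(track: CreTrack, pad: int) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    iv = track.intervals.copy()
    iv["start"] = iv["start"] - pad
    iv["end"] = iv["end"] + pad
    merged = merge_intervals(iv)
    return {chrom: (grp["start"].to_numpy(), grp["end"].to_numpy())
            for chrom, grp in merged.groupby("chrom")}


def snp_overlaps(snps: pd.DataFrame, track: CreTrack, pad: int = 500) -> np.ndarray:
    """Boolean per SNP: position within ``pad`` bp of any element of the track.

    ``snps`` needs columns ``chrom`` and ``pos``.
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    by_chrom = _merged_per_chrom(track, pad)
    chroms = snps["chrom"].to_numpy()
    pos = snps["pos"].to_numpy()
    out = np.zeros(len(snps), dtype=bool)
    for chrom in np.unique(chroms):
        if chrom not in by_chrom:
            continue
        starts, ends = by_chrom[chrom]
        m = chroms == chrom
        p = pos[m]
        idx = np.searchsorted(starts, p, side="right") - 1
        hit = (idx >= 0) & (p < ends[np.clip(idx, 0, None)])
        out[m] = hit
    return out


def intervening_insulator(snp_pos: int, tss_pos: int, track: CreTrack,
                          chrom: str | None = None) -> bool:
    """True iff some insulator midpoint lies strictly between SNP and TSS.

    ``snp_pos == tss_pos`` is a degenerate span and returns False.
    """
    if snp_pos == tss_pos:
        return False
    iv = track.intervals
    if chrom is not None:
        iv = iv[iv["chrom"] == chrom]
    mids = ((iv["start"].to_numpy() + iv["end"].to_numpy()) // 2)
    lo, hi = min(snp_pos, tss_pos), max(snp_pos, tss_pos)
    return bool(np.any((mids > lo) & (mids < hi)))


def _midpoints_per_chrom(intervals: pd.DataFrame) -> dict[str, np.ndarray]:
    return {chrom: np.sort((grp["start"].to_numpy() + grp["end"].to_numpy()) // 2)
            for chrom, grp in intervals.groupby("chrom")}


def intervening_flags(pos_a: np.ndarray, pos_b: np.ndarray, chroms: np.ndarray,
                      intervals: pd.DataFrame) -> np.ndarray:
    """Vectorized strictly-between midpoint test for many (a, b) pairs."""
    mids = _midpoints_per_chrom(intervals)
    lo = np.minimum(pos_a, pos_b)
    hi = np.maximum(pos_a, pos_b)
    out = np.zeros(len(lo), dtype=bool)
    for chrom in np.unique(chroms):
        if chrom not in mids:
            continue
        m = chroms == chrom
        mm = mids[chrom]
        left = np.searchsorted(mm, lo[m], side="right")
        right = np.searchsorted(mm, hi[m], side="left")
        out[m] = (right > left) & (lo[m] != hi[m])
    return out


def background_snps(snp_map: pd.DataFrame, gene_models: pd.DataFrame,
                    seed: int = 0, window: int = 1_000_000) -> pd.DataFrame:
    """Background SNP set: every SNP cis to >= 1 gene, with one random gene each.

    A SNP qualifies if it lies within ``window`` of a gene's TSS/TES or
    inside the gene body (the cis window contains the body).  SNPs cis to
    several genes are assigned uniformly at random to one of them.
    """
    rng = np.random.default_rng(seed)
    gm = annotate_tss_tes(gene_models) if "tss" not in gene_models else gene_models
    rows = []
    pos = snp_map["pos"].to_numpy()
    chroms = snp_map["chrom"].to_numpy()
    snp_ids = snp_map["snp_id"].to_numpy()
    for _, snp_chrom in enumerate(np.unique(chroms)):
        m = chroms == snp_chrom
        genes_here = gm[gm["chrom"] == snp_chrom]
        if len(genes_here) == 0:
            continue
        bounds = np.array([cis_bounds(g, window) for _, g in genes_here.iterrows()])
        gene_ids = genes_here["gene_id"].to_numpy()
        for sid, p in zip(snp_ids[m], pos[m]):
            inside = (bounds[:, 0] <= p) & (p <= bounds[:, 1])
            hits = gene_ids[inside]
            if len(hits) == 0:
                continue
            gene = hits[0] if len(hits) == 1 else hits[rng.integers(0, len(hits))]
            rows.append((sid, gene, snp_chrom, int(p)))
    return pd.DataFrame(rows, columns=["snp_id", "gene_id", "chrom", "pos"])


def build_snp_pairs(eqtl_records: pd.DataFrame, background: pd.DataFrame,
                    gene_models: pd.DataFrame, hotspot_intervals: pd.DataFrame,
                    snp_map: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Tier-1/tier-2 eQTL SNP pairs and random cis background pairs, with flags.

    eQTL pairs: one (tier1, tier2) pair per gene holding both tiers (the
    caller filters tier-2 records for significance beforehand).  Background
    pairs: two random cis SNPs per gene with >= 2 cis SNPs.  Each pair gets
    inter-SNP distance, intervening-hotspot and intervening-TSS flags (all
    genes' TSSs count as intervening features).
    """
    rng = np.random.default_rng(seed)
    gm = annotate_tss_tes(gene_models) if "tss" not in gene_models else gene_models
    pos_of = dict(zip(snp_map["snp_id"], snp_map["pos"]))
    rows = []
    for gene_id, grp in eqtl_records.groupby("GENE"):
        t1 = grp[grp["TIER"] == 1]
        t2 = grp[grp["TIER"] == 2]
        if len(t1) == 0 or len(t2) == 0:
            continue
        a, b = t1.iloc[0], t2.iloc[0]
        gene = gm[gm["gene_id"] == gene_id].iloc[0]
        rows.append((gene_id, gene["chrom"], a["RSID"], b["RSID"],
                     int(a["RSCOORD"]), int(b["RSCOORD"]), "eqtl-tier1-tier2"))
    for gene_id, grp in background.groupby("gene_id"):
        if len(grp) < 2:
            continue
        pick = rng.choice(len(grp), size=2, replace=False)
        a, b = grp.iloc[pick[0]], grp.iloc[pick[1]]
        if a["pos"] == b["pos"]:
            continue
        rows.append((gene_id, a["chrom"], a["snp_id"], b["snp_id"],
                     int(a["pos"]), int(b["pos"]), "background"))
    pairs = pd.DataFrame(rows, columns=["gene_id", "chrom", "snp_a", "snp_b",
                                        "pos_a", "pos_b", "source"])
    if len(pairs) == 0:
        return pairs.assign(distance=[], hotspot=[], intervening_tss=[])
    pairs["distance"] = np.abs(pairs["pos_a"] - pairs["pos_b"])
    pairs["hotspot"] = intervening_flags(
        pairs["pos_a"].to_numpy(), pairs["pos_b"].to_numpy(),
        pairs["chrom"].to_numpy(), hotspot_intervals)
    tss_iv = pd.DataFrame({"chrom": gm["chrom"], "start": gm["tss"],
                           "end": gm["tss"] + 1})
    pairs["intervening_tss"] = intervening_flags(
        pairs["pos_a"].to_numpy(), pairs["pos_b"].to_numpy(),
        pairs["chrom"].to_numpy(), tss_iv)
    return pairs


def annotate_snps(snps: pd.DataFrame, tracks: dict[str, CreTrack],
                  pad: int = 500) -> pd.DataFrame:
    """0/1 overlap matrix: one row per SNP, one column per track."""
    out = snps[["snp_id", "chrom", "pos"]].copy().reset_index(drop=True)
    for tid, track in tracks.items():
        out[tid] = snp_overlaps(out[["chrom", "pos"]], track, pad=pad).astype(int)
    return out
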