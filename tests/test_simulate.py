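"""Tests for the synthetic-data generator: LD structure, planted effects,
CRE placement and determinism."""

import numpy as np
import pandas as pd
import pytest

from eqtlcre.overlap import snp_overlaps
from eqtlcre.simulate import (annotate_truth_cre, make_gene_models,
                              random_eqtl_plan, simulate_cre_tracks,
                              simulate_expression, simulate_genotypes,
                              simulate_recomb_map, simulate_study_set)
from eqtlcre.tiers import ld_blocks


class TestRecombMap:
    def test_hotspot_placement_every_third_interval(self):
        rmap = simulate_recomb_map(7, hotspot_every=3, background_rate=0.1,
                                   hotspot_rate=2.0)
        np.testing.assert_allclose(rmap.rates, [0.1, 0.1, 2.0, 0.1, 0.1, 2.0])

    def test_flat_map_gives_single_block(self):
        rmap = simulate_recomb_map(10, hotspot_every=3, background_rate=0.5,
                                   hotspot_rate=0.5)
        assert ld_blocks(rmap, rate_threshold=0.9).n_blocks == 1

    def test_deterministic(self):
        a = simulate_recomb_map(20, seed=5)
        b = simulate_recomb_map(20, seed=5)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.rates, b.rates)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            simulate_recomb_map(7, spacing=0)
        with pytest.raises(ValueError):
            simulate_recomb_map(1)


class TestGenotypes:
    def test_zero_ld_gives_near_independent_snps(self):
        rmap = simulate_recomb_map(40)
        gt = simulate_genotypes(500, rmap, within_block_r2=0.0, seed=3)
        c = np.corrcoef(gt.dosages.T)
        off = np.abs(c[~np.eye(len(c), dtype=bool)])
        assert off.mean() < 0.1

    def test_within_block_correlation_tracks_parameter(self):
        rmap = simulate_recomb_map(40)
        gt = simulate_genotypes(500, rmap, within_block_r2=0.8, seed=3,
                                maf_range=(0.3, 0.4))
        blocks = ld_blocks(rmap).block_index
        c = np.corrcoef(gt.dosages.T)
        same = (blocks[:, None] == blocks[None, :]) & ~np.eye(len(blocks), dtype=bool)
        cross = blocks[:, None] != blocks[None, :]
        assert np.abs(c[same]).mean() > 0.5
        assert np.abs(c[cross]).mean() < 0.1

    def test_half_maf_target_realized_within_binomial_bounds(self):
        rmap = simulate_recomb_map(30)
        gt = simulate_genotypes(500, rmap, maf_range=(0.5, 0.5), seed=9)
        freq = gt.dosages.mean(axis=0) / 2
        assert np.all((freq >= 0.4) & (freq <= 0.6))

    def test_maf_recomputable_and_bounded(self):
        rmap = simulate_recomb_map(25)
        gt = simulate_genotypes(120, rmap, seed=4)
        freq = gt.dosages.mean(axis=0) / 2
        np.testing.assert_allclose(gt.maf, np.minimum(freq, 1 - freq), atol=1e-12)
        assert np.all(gt.maf > 0) and np.all(gt.maf <= 0.5)
        assert np.all((gt.dosages >= 0) & (gt.dosages <= 2))

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            simulate_genotypes(0, simulate_recomb_map(10))

    def test_deterministic(self):
        rmap = simulate_recomb_map(15)
        a = simulate_genotypes(50, rmap, seed=7)
        b = simulate_genotypes(50, rmap, seed=7)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        assert a.snp_ids == b.snp_ids


def _two_celltype_setup(n_genes=5, n_samples=200, seed=0):
    rmaps, gts = {}, {}
    chroms, tss = [], []
    for i in range(n_genes):
        chrom = f"chr{i+1}"
        rmap = simulate_recomb_map(30, chromosome=chrom)
        rmaps[chrom] = rmap
        gts[chrom] = simulate_genotypes(n_samples, rmap, seed=seed + i)
        chroms.append(chrom)
        tss.append(int(rmap.positions[15]))
    gm = make_gene_models(chroms, tss)
    blocks = {c: ld_blocks(r).block_index for c, r in rmaps.items()}
    return rmaps, gts, gm, blocks


class TestExpression:
    def test_null_traits_uncorrelated_with_dosages(self):
        _, gts, gm, blocks = _two_celltype_setup(n_genes=20, n_samples=200, seed=2)
        plan = pd.DataFrame(columns=["gene_id", "snp_id", "chrom", "pos",
                                     "tier", "beta", "target_r2",
                                     "bivariate_class"])
        expr, truth = simulate_expression({"A": gts, "B": gts}, gm, plan,
                                          n_confounders=0, seed=5)
        assert len(truth) == 0
        worst = 0.0
        for _, gene in gm.iterrows():
            y = expr["A"][gene["gene_id"]].to_numpy()
            d = gts[gene["chrom"]].dosages
            r = np.abs([np.corrcoef(y, d[:, j])[0, 1] for j in range(d.shape[1])])
            worst = max(worst, r.max())
        assert worst < 0.25

    def test_planted_r2_realized(self):
        _, gts, gm, blocks = _two_celltype_setup(n_genes=8, n_samples=500, seed=3)
        plan = random_eqtl_plan(gm, gts, blocks, eqtl_fraction=1.0,
                                two_tier_fraction=0.0, effect_r2=0.5, seed=1)
        expr, truth = simulate_expression({"A": gts, "B": gts}, gm, plan,
                                          n_confounders=0, seed=8)
        for _, row in truth[truth["beta_a"] != 0].iterrows():
            gt = gts[row["chrom"]]
            g = gt.dosages[:, gt.snp_ids.index(row["snp_id"])]
            y = expr["A"][row["gene_id"]].to_numpy()
            r2 = np.corrcoef(y, g)[0, 1] ** 2
            assert abs(r2 - 0.5) < 0.1

    def test_opposite_class_flips_effect_sign(self):
        _, gts, gm, blocks = _two_celltype_setup(n_genes=10, n_samples=300, seed=4)
        plan = random_eqtl_plan(gm, gts, blocks, eqtl_fraction=1.0,
                                two_tier_fraction=0.0, effect_r2=0.3,
                                class_mix={"A-opposite-B": 1.0}, seed=2)
        expr, truth = simulate_expression({"A": gts, "B": gts}, gm, plan,
                                          n_confounders=0, seed=9)
        for _, row in truth.iterrows():
            gt = gts[row["chrom"]]
            g = gt.dosages[:, gt.snp_ids.index(row["snp_id"])]
            slope_a = np.polyfit(g, expr["A"][row["gene_id"]], 1)[0]
            slope_b = np.polyfit(g, expr["B"][row["gene_id"]], 1)[0]
            assert np.sign(slope_a) == -np.sign(slope_b)

    def test_snp_outside_cis_window_rejected(self):
        _, gts, gm, _ = _two_celltype_setup(n_genes=2, n_samples=50, seed=5)
        plan = pd.DataFrame([{
            "gene_id": gm["gene_id"].iloc[0], "snp_id": "far", "chrom": "chr1",
            "pos": int(gm["tss"].iloc[0]) + 5_000_000, "tier": 1,
            "beta": 0.5, "target_r2": np.nan, "bivariate_class": "stable"}])
        with pytest.raises(ValueError, match="cis window"):
            simulate_expression({"A": gts, "B": gts}, gm, plan)


class TestCreTracks:
    def test_zero_specific_fraction_makes_tracks_identical(self, small_study):
        study = small_study
        snp_map = study.snp_map()
        tracks = simulate_cre_tracks(study.gene_models, snp_map, study.truth,
                                     ["A", "B"], specific_fraction=0.0, seed=1)
        for cls in ("activating", "repressive", "insulator"):
            pd.testing.assert_frame_equal(tracks[f"{cls}_A"].intervals,
                                          tracks[f"{cls}_B"].intervals)

    def test_no_enrichment_balances_causal_and_background_overlap(self, small_study):
        study = small_study
        snp_map = study.snp_map()
        tracks = simulate_cre_tracks(study.gene_models, snp_map, study.truth,
                                     ["A", "B"], eqtl_enrichment=1.0,
                                     specific_fraction=0.0,
                                     background_rate=0.3, seed=2)
        causal = snp_map["snp_id"].isin(study.truth["snp_id"]).to_numpy()
        hit = snp_overlaps(snp_map[["chrom", "pos"]],
                           tracks["activating_A"], pad=0)
        p1, n1 = hit[causal].mean(), causal.sum()
        p2, n2 = hit[~causal].mean(), (~causal).sum()
        pool = hit.mean()
        se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
        assert abs(p1 - p2) < 2 * se + 1e-9

    def test_empty_gene_set_rejected(self, small_study):
        with pytest.raises(ValueError, match="empty gene set"):
            simulate_cre_tracks(small_study.gene_models.iloc[0:0],
                                small_study.snp_map(), small_study.truth,
                                ["A", "B"])

    def test_truth_flags_recomputable_from_tracks(self, small_study):
        """Conservation: membership flags round-trip from the emitted intervals."""
        study = small_study
        re_annot = annotate_truth_cre(
            study.truth.drop(columns=[c for c in study.truth.columns
                                      if c.startswith("in_")]),
            study.tracks)
        pd.testing.assert_frame_equal(re_annot, study.truth)


class TestStudySet:
    def test_full_determinism(self):
        a = simulate_study_set(n_genes=6, n_samples=60, seed=21)
        b = simulate_study_set(n_genes=6, n_samples=60, seed=21)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        for sid in a.expression:
            pd.testing.assert_frame_equal(a.expression[sid], b.expression[sid])
        for tid in a.tracks:
            pd.testing.assert_frame_equal(a.tracks[tid].intervals,
                                          b.tracks[tid].intervals)
        pd.testing.assert_frame_equal(a.gwas, b.gwas)

    def test_structure(self, small_study):
        study = small_study
        assert set(study.genotypes) == {"A_discovery", "A_replication", "B_paired"}
        # paired design: B shares donors with the discovery cohort
        ga = study.genotypes["A_discovery"]["chr1"]
        gb = study.genotypes["B_paired"]["chr1"]
        assert ga.sample_ids == gb.sample_ids
        gr = study.genotypes["A_replication"]["chr1"]
        assert set(gr.sample_ids).isdisjoint(ga.sample_ids)
        # tiers within a gene are distinct and snps unique
        dup = study.truth.groupby(["gene_id", "snp_id"]).size()
        assert (dup == 1).all()
        tiers = study.truth.groupby("gene_id")["tier"].nunique()
        counts = study.truth.groupby("gene_id").size()
        assert (tiers == counts).all()
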