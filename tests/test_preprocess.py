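"""Tests for genotype QC and the expression normalization pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eqtlcre.preprocess import (ExpressionMatrix, cluster_probes,
                                filter_genotypes, inverse_normal_transform,
                                normalize_expression, per_population_normalize,
                                remove_pcs)
from eqtlcre.simulate import GenotypeMatrix


def _gt_from_dosages(dos):
    dos = np.asarray(dos, dtype=float)
    m = dos.shape[1]
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(dos.shape[0])],
        snp_ids=[f"snp{j}" for j in range(m)],
        chromosomes=np.full(m, "chr1", dtype=object),
        positions=np.arange(m, dtype=np.int64) * 1000,
        major=np.full(m, "A", dtype=object),
        minor=np.full(m, "C", dtype=object),
        dosages=dos)


class TestGenotypeQC:
    def test_perfect_hwe_retained_at_any_alpha(self):
        dos = np.repeat([0.0, 1.0, 2.0], [25, 50, 25])[:, None]
        gt = filter_genotypes(_gt_from_dosages(dos), hwe_alpha=0.999)
        assert gt.n_snps == 1

    def test_het_deficit_removed(self):
        """(50, 0, 50) genotype counts give chi-square 100, removed at 1e-4."""
        dos = np.repeat([0.0, 2.0], [50, 50])[:, None]
        stat = 100.0
        assert stats.chi2.sf(stat, 1) < 1e-4
        gt = filter_genotypes(_gt_from_dosages(dos), hwe_alpha=1e-4)
        assert gt.n_snps == 0

    def test_clean_input_is_identity(self, rng):
        dos = rng.integers(0, 3, size=(40, 6)).astype(float)
        gt = filter_genotypes(_gt_from_dosages(dos), hwe_alpha=0.0)
        np.testing.assert_array_equal(gt.dosages, dos)

    def test_missing_dosages_mean_imputed(self, rng):
        dos = rng.integers(0, 3, size=(60, 40)).astype(float)
        dos[3, 1] = np.nan  # sample 3 call rate 39/40, above threshold
        gt = filter_genotypes(_gt_from_dosages(dos), hwe_alpha=0.0)
        expected = np.nanmean(dos[:, 1])
        assert gt.n_samples == 60
        assert gt.dosages[3, 1] == pytest.approx(expected)

    def test_all_samples_removed_raises(self):
        dos = np.full((5, 3), np.nan)
        with pytest.raises(ValueError, match="all samples"):
            filter_genotypes(_gt_from_dosages(dos))


class TestNormalize:
    def test_output_columns_are_standard_normal_quantile_sets(self, rng):
        """Tie-free columns map exactly to the Phi^-1((i-0.5)/n) quantile set.

        The cross-array quantile step can tie two samples at the same trait
        (both rank it identically within their arrays); those columns carry
        average-rank ties instead of the exact quantile set, so the exact
        check applies to the tie-free columns.
        """
        n, p = 10, 400
        raw = ExpressionMatrix(pd.DataFrame(
            rng.lognormal(3, 1, size=(n, p)),
            columns=[f"t{i}" for i in range(p)]))
        out = normalize_expression(raw)
        expected = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        checked = 0
        for col in out.values.columns:
            v = np.sort(out.values[col].to_numpy())
            if len(np.unique(v)) == n:
                np.testing.assert_allclose(v, expected, atol=1e-12)
                checked += 1
        assert checked > p / 2

    def test_invariant_under_monotone_intensity_transform(self, rng):
        """A strictly increasing transform of the raw intensities changes
        nothing downstream: every step acts on ranks."""
        vals = rng.lognormal(3, 1, size=(25, 40))
        cols = [f"t{i}" for i in range(40)]
        out1 = normalize_expression(ExpressionMatrix(pd.DataFrame(vals, columns=cols)))
        out2 = normalize_expression(ExpressionMatrix(pd.DataFrame(vals ** 3, columns=cols)))
        pd.testing.assert_frame_equal(out1.values, out2.values)

    def test_inverse_normal_transform_is_exactly_rank_preserving(self, rng):
        x = rng.lognormal(0, 2, size=200)
        y = inverse_normal_transform(x)
        assert stats.spearmanr(x, y).statistic == pytest.approx(1.0)

    def test_knn_imputation_matches_bruteforce_oracle(self, rng):
        """Each imputed cell equals the mean of its k nearest trait columns."""
        from eqtlcre.preprocess import _knn_impute_columns
        vals = rng.standard_normal((40, 12))
        mask = rng.random(vals.shape) < 0.05
        vals[mask] = np.nan
        k = 5
        got = _knn_impute_columns(vals, k)
        obs = ~np.isnan(vals)
        for i, j in zip(*np.nonzero(mask)):
            dists = []
            for j2 in range(vals.shape[1]):
                if j2 == j:
                    continue
                both = obs[:, j] & obs[:, j2]
                if both.sum() < 2:
                    continue
                dists.append((np.mean((vals[both, j] - vals[both, j2]) ** 2), j2))
            dists.sort()
            donors = [vals[i, j2] for _, j2 in dists[:k] if obs[i, j2]]
            expected = np.mean(donors) if donors else np.nanmean(vals[:, j])
            assert got[i, j] == pytest.approx(expected)

    def test_constant_trait_dropped_with_warning(self, rng):
        vals = rng.lognormal(3, 1, size=(20, 3))
        vals[:, 1] = 5.0
        raw = ExpressionMatrix(pd.DataFrame(vals, columns=list("abc")))
        with pytest.warns(UserWarning, match="constant"):
            out = normalize_expression(raw)
        assert list(out.values.columns) == ["a", "c"]


class TestRemovePcs:
    def _quantile_expr(self, rng, n=60, p=20):
        vals = rng.standard_normal((n, p))
        df = pd.DataFrame(np.column_stack(
            [inverse_normal_transform(vals[:, j]) for j in range(p)]),
            columns=[f"t{j}" for j in range(p)])
        return ExpressionMatrix(df, stage="quantile")

    def test_delta_one_removes_nothing(self, rng):
        expr = self._quantile_expr(rng)
        out, report = remove_pcs(expr, pve_delta=1.0)
        assert report.n_pcs_removed == 0
        renorm = np.column_stack([inverse_normal_transform(expr.values[c])
                                  for c in expr.values.columns])
        np.testing.assert_allclose(out.values.to_numpy(), renorm, atol=1e-12)

    def test_single_planted_factor_removed(self, rng):
        n, p = 100, 30
        factor = rng.standard_normal(n)
        load = rng.standard_normal(p) * 2.0
        vals = np.outer(factor, load) + rng.standard_normal((n, p))
        df = pd.DataFrame(np.column_stack(
            [inverse_normal_transform(vals[:, j]) for j in range(p)]),
            columns=[f"t{j}" for j in range(p)])
        out, report = remove_pcs(ExpressionMatrix(df, stage="quantile"),
                                 pve_delta=0.01)
        assert report.n_pcs_removed == 1
        corrs = [abs(np.corrcoef(out.values[c], factor)[0, 1])
                 for c in out.values.columns]
        assert max(corrs) < 0.35 and np.mean(corrs) < 0.15

    def test_residuals_orthogonal_to_removed_pcs(self, rng):
        n, p = 80, 25
        factor = rng.standard_normal(n)
        vals = np.outer(factor, rng.standard_normal(p) * 3) \
            + rng.standard_normal((n, p))
        df = pd.DataFrame(vals, columns=[f"t{j}" for j in range(p)])
        expr = ExpressionMatrix(df, stage="quantile")
        out, report = remove_pcs(expr, pve_delta=0.01, renormalize=False)
        assert report.n_pcs_removed >= 1
        X = df.to_numpy() - df.to_numpy().mean(axis=0)
        U, s, _ = np.linalg.svd(X, full_matrices=False)
        scores = U[:, :report.n_pcs_removed] * s[:report.n_pcs_removed]
        proj = scores.T @ out.values.to_numpy()
        assert np.max(np.abs(proj)) < 1e-8 * np.abs(X).max() * len(X)

    def test_pve_sequence_non_increasing(self, rng):
        _, report = remove_pcs(self._quantile_expr(rng), pve_delta=0.01)
        assert all(a >= b - 1e-12 for a, b in
                   zip(report.pve, report.pve[1:]))

    def test_idempotence(self, rng):
        expr = self._quantile_expr(rng, n=80, p=25)
        once, r1 = remove_pcs(expr, pve_delta=0.02)
        twice, r2 = remove_pcs(once, pve_delta=0.02)
        assert r2.n_pcs_removed == 0

    def test_invalid_delta(self, rng):
        with pytest.raises(ValueError):
            remove_pcs(self._quantile_expr(rng), pve_delta=0.0)

    def test_recovers_planted_confounders(self):
        """Leading PCs align with the generator's latent confounders."""
        from eqtlcre.simulate import (make_gene_models, simulate_expression,
                                      simulate_genotypes, simulate_recomb_map)
        rmaps, gts, chroms, tss = {}, {}, [], []
        for i in range(30):
            chrom = f"chr{i+1}"
            rmap = simulate_recomb_map(10, chromosome=chrom)
            gts[chrom] = simulate_genotypes(150, rmap, seed=i)
            chroms.append(chrom)
            tss.append(int(rmap.positions[5]))
        gm = make_gene_models(chroms, tss)
        plan = pd.DataFrame(columns=["gene_id", "snp_id", "chrom", "pos",
                                     "tier", "beta", "target_r2",
                                     "bivariate_class"])
        expr, _, conf = simulate_expression(
            {"A": gts}, gm, plan, n_confounders=2, confounder_var_frac=0.5,
            seed=33, return_confounders=True)
        df = pd.DataFrame(np.column_stack(
            [inverse_normal_transform(expr["A"][c]) for c in expr["A"].columns]),
            columns=expr["A"].columns)
        _, report = remove_pcs(ExpressionMatrix(df, stage="quantile"),
                               pve_delta=0.01)
        X = df.to_numpy() - df.to_numpy().mean(axis=0)
        U, s, _ = np.linalg.svd(X, full_matrices=False)
        k = max(report.n_pcs_removed, 2)
        scores = U[:, :k] * s[:k]
        for c in range(conf["A"].shape[1]):
            best = max(abs(np.corrcoef(scores[:, j], conf["A"][:, c])[0, 1])
                       for j in range(k))
            assert best >= 0.9


class TestClusterProbes:
    def _resid(self, vals, names):
        df = pd.DataFrame(np.column_stack(
            [inverse_normal_transform(v) for v in vals]), columns=names)
        return ExpressionMatrix(df, stage="residual")

    def test_identical_probes_form_one_cluster(self, rng):
        base = rng.standard_normal(200)
        expr = self._resid([base, base], ["p1", "p2"])
        mapping = pd.DataFrame({"probe_id": ["p1", "p2"], "gene_id": ["g", "g"]})
        out = cluster_probes(expr, mapping)
        assert list(out.values.columns) == ["g.c1"]
        np.testing.assert_allclose(out.values["g.c1"], expr.values["p1"])

    def test_anticorrelated_probes_split(self, rng):
        base = rng.standard_normal(200)
        noisy = -0.9 * base + np.sqrt(1 - 0.81) * rng.standard_normal(200)
        expr = self._resid([base, noisy], ["p1", "p2"])
        mapping = pd.DataFrame({"probe_id": ["p1", "p2"], "gene_id": ["g", "g"]})
        out = cluster_probes(expr, mapping)
        assert len(out.values.columns) == 2

    def test_single_probe_passthrough(self, rng):
        expr = self._resid([rng.standard_normal(50)], ["p1"])
        mapping = pd.DataFrame({"probe_id": ["p1"], "gene_id": ["g"]})
        out = cluster_probes(expr, mapping)
        np.testing.assert_allclose(out.values["g.c1"], expr.values["p1"])

    def test_invalid_max_clusters(self, rng):
        expr = self._resid([rng.standard_normal(50)], ["p1"])
        with pytest.raises(ValueError):
            cluster_probes(expr, pd.DataFrame({"probe_id": ["p1"],
                                               "gene_id": ["g"]}),
                           max_clusters=0)


class TestPerPopulation:
    def test_shifted_populations_both_centered(self, rng):
        pops = pd.Series(["x"] * 30 + ["y"] * 30, index=range(60))
        vals = rng.standard_normal((60, 4))
        vals[30:] += 5.0
        expr = ExpressionMatrix(pd.DataFrame(vals, index=range(60),
                                             columns=list("abcd")))
        out = per_population_normalize(expr, pops)
        for pop in ("x", "y"):
            sub = out.values[(pops == pop).to_numpy()]
            assert np.abs(sub.mean(axis=0)).max() < 1e-8

    def test_rank_invariance_within_population(self, rng):
        pops = pd.Series(["x"] * 20, index=range(20))
        vals = rng.standard_normal((20, 3))
        a = per_population_normalize(
            ExpressionMatrix(pd.DataFrame(vals, index=range(20),
                                          columns=list("abc"))), pops)
        b = per_population_normalize(
            ExpressionMatrix(pd.DataFrame(2 * vals + 3, index=range(20),
                                          columns=list("abc"))), pops)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_singleton_population_rejected(self, rng):
        pops = pd.Series(["x"] * 19 + ["y"], index=range(20))
        expr = ExpressionMatrix(pd.DataFrame(rng.standard_normal((20, 3)),
                                             index=range(20), columns=list("abc")))
        with pytest.raises(ValueError):
            per_population_normalize(expr, pops)
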