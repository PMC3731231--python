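"""Tests for replication calls, binned curves, exact categorical tests and
the logistic enrichment models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize

from eqtlcre.replication import (binned_curve, call_replication, fisher_test,
                                 fit_enrichment, mcnemar_test)


def _records(rows):
    return pd.DataFrame(rows)


class TestCallReplication:
    def _discovery(self):
        return _records([
            {"GENE": "g1", "RSID": "a", "MAF": 0.3, "TIER": 1},
            {"GENE": "g2", "RSID": "b", "MAF": 0.3, "TIER": 1},
            {"GENE": "g3", "RSID": "c", "MAF": 0.01, "TIER": 1},
            {"GENE": "g4", "RSID": "d", "MAF": 0.3, "TIER": 1},
        ])

    def _targets(self):
        within = pd.DataFrame({
            "gene_id": ["g1", "g2", "g4"], "snp_id": ["a", "b", "d"],
            "log10bf": [3.0, 0.2, 2.0], "maf": [0.3, 0.3, 0.3]})
        between = pd.DataFrame({
            "gene_id": ["g1", "g4"], "snp_id": ["a", "d"],
            "log10bf": [0.1, 2.5], "maf": [0.3, 0.3]})
        return {"w": within, "b": between}

    def test_statuses_and_categories(self):
        calls = call_replication(self._discovery(), self._targets(),
                                 within_study="w", between_study="b",
                                 bf_threshold=1.0, maf_min=0.05)
        by_gene = calls.set_index("GENE")
        # g1 replicates within, fails between -> cell-specific
        assert by_gene.loc["g1", "category"] == "cell-specific"
        # g2 absent from the between target -> untested overall
        assert by_gene.loc["g2", "status_w"] == "not-replicated"
        assert by_gene.loc["g2", "category"] == "untested"
        # g3 fails the discovery MAF filter everywhere
        assert by_gene.loc["g3", "status_w"] == "untested"
        # g4 replicates in both
        assert by_gene.loc["g4", "category"] == "within-and-between"

    def test_low_target_maf_is_untested(self):
        targets = {"w": pd.DataFrame({"gene_id": ["g1"], "snp_id": ["a"],
                                      "log10bf": [5.0], "maf": [0.01]}),
                   "b": pd.DataFrame(columns=["gene_id", "snp_id",
                                              "log10bf", "maf"])}
        calls = call_replication(self._discovery().iloc[:1], targets,
                                 within_study="w", between_study="b")
        assert calls.iloc[0]["status_w"] == "untested"


class TestBinnedCurve:
    def test_all_successes(self, rng):
        x = rng.uniform(0, 10, 100)
        out = binned_curve(x, np.ones(100, dtype=bool), n_bins=5)
        filled = out[~out["empty"]]
        assert (filled["fraction"] == 1.0).all()
        assert np.allclose(filled["ci_high"], 1.0, atol=1e-9)

    def test_wilson_interval_frozen_value(self):
        """8/10 successes give the Wilson 95% interval (0.490, 0.943)."""
        x = np.linspace(0, 1, 10)
        y = np.array([1] * 8 + [0] * 2, dtype=bool)
        out = binned_curve(x, y, n_bins=2)
        # force a single populated bin by using identical x
        out = binned_curve(np.zeros(10), y, n_bins=2)
        row = out[out["n"] == 10].iloc[0]
        assert row["ci_low"] == pytest.approx(0.490, abs=0.005)
        assert row["ci_high"] == pytest.approx(0.943, abs=0.005)

    def test_no_trend_when_independent(self, rng):
        x = rng.uniform(0, 1, 2000)
        y = rng.random(2000) < 0.5
        out = binned_curve(x, y, n_bins=30)
        filled = out[~out["empty"]]
        rho = stats.spearmanr(filled["bin"], filled["fraction"]).statistic
        assert abs(rho) < 0.5

    def test_empty_bins_flagged(self):
        x = np.array([0.0, 0.0, 10.0])
        out = binned_curve(x, np.array([1, 0, 1], dtype=bool), n_bins=5)
        assert out["empty"].sum() == 3
        assert np.isnan(out[out["empty"]]["fraction"]).all()

    def test_min_bins(self):
        with pytest.raises(ValueError):
            binned_curve(np.arange(4.0), np.ones(4, dtype=bool), n_bins=1)


class TestMcNemar:
    def test_frozen_exact_value(self):
        """Discordant counts (2, 8) give 2 * P(X <= 2 | n=10) = 0.109375."""
        a = np.array([1] * 2 + [0] * 8 + [1] * 5 + [0] * 5, dtype=bool)
        b = np.array([0] * 2 + [1] * 8 + [1] * 5 + [0] * 5, dtype=bool)
        assert mcnemar_test(a, b) == pytest.approx(0.109375, abs=1e-12)

    def test_symmetric_discordance_gives_one(self):
        a = np.array([1] * 5 + [0] * 5, dtype=bool)
        b = ~a
        assert mcnemar_test(a, b) == 1.0

    def test_agreement_only_gives_one(self):
        a = np.array([1, 1, 0, 0], dtype=bool)
        assert mcnemar_test(a, a) == 1.0

    def test_matches_exhaustive_binomial_oracle(self):
        """Exact two-sided binomial p for every discordant split up to 30."""
        from math import comb
        for n in range(1, 31):
            for b10 in range(n + 1):
                pmf = np.array([comb(n, k) * 0.5 ** n for k in range(n + 1)])
                oracle = float(pmf[pmf <= pmf[b10] * (1 + 1e-12)].sum())
                a = np.array([1] * b10 + [0] * (n - b10), dtype=bool)
                b = ~a
                assert mcnemar_test(a, b) == pytest.approx(min(1.0, oracle),
                                                           abs=1e-9)


class TestFisher:
    def test_sample_odds_ratio(self):
        orr, p = fisher_test([[10, 5], [2, 20]])
        assert orr == pytest.approx(20.0)

    def test_independence_table(self):
        orr, p = fisher_test([[10, 10], [10, 10]])
        assert orr == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_zero_margin(self):
        orr, p = fisher_test([[0, 0], [5, 7]])
        assert p == 1.0
        assert np.isnan(orr)

    def test_matches_hypergeometric_enumeration(self, rng):
        """Two-sided p equals summed hypergeometric pmf over the table family."""
        for _ in range(50):
            t = rng.integers(0, 13, size=(2, 2))
            if t.sum() == 0 or t.sum(0).min() == 0 or t.sum(1).min() == 0:
                continue
            a, b = int(t[0, 0]), int(t[0, 1])
            c, d = int(t[1, 0]), int(t[1, 1])
            n, r1, c1 = a + b + c + d, a + b, a + c
            lo, hi = max(0, r1 + c1 - n), min(r1, c1)
            support = np.arange(lo, hi + 1)
            pmf = stats.hypergeom.pmf(support, n, r1, c1)
            oracle = float(pmf[pmf <= pmf[a - lo] * (1 + 1e-7)].sum())
            _, p = fisher_test(t)
            assert p == pytest.approx(min(1.0, oracle), abs=1e-9)


class TestEnrichment:
    def _eq2_frame(self, rng, n=5000, enrich=1.0):
        is_eqtl = (rng.random(n) < 0.3).astype(float)
        dist = rng.uniform(-5e5, 5e5, n)
        expr = rng.standard_normal(n)
        base = 0.15
        p = np.where(is_eqtl == 1, min(0.95, base * enrich), base)
        overlap = (rng.random(n) < p).astype(float)
        return pd.DataFrame({"overlap": overlap, "tss_dist_signed": dist,
                             "tss_dist_abs": np.abs(dist),
                             "expression": expr, "is_eqtl": is_eqtl})

    def test_null_indicator_not_significant(self, rng):
        fit = fit_enrichment("eq2", self._eq2_frame(rng, enrich=1.0))
        assert abs(fit.params.loc["is_eqtl", "z"]) < 3

    def test_planted_enrichment_detected(self, rng):
        fit = fit_enrichment("eq2", self._eq2_frame(rng, enrich=3.0))
        assert fit.coef("is_eqtl") > 0
        assert fit.pvalue("is_eqtl") < 0.01

    def test_coefficients_match_generic_mle_oracle(self, rng):
        df = self._eq2_frame(rng, n=800, enrich=2.0)
        fit = fit_enrichment("eq2", df)
        X = np.column_stack([
            np.ones(len(df)), df["tss_dist_signed"] / 1e6,
            df["tss_dist_abs"] / 1e6, df["expression"], df["is_eqtl"]])
        y = df["overlap"].to_numpy()

        def nll(beta):
            eta = X @ beta
            return np.sum(np.logaddexp(0, eta) - y * eta)

        res = minimize(nll, np.zeros(X.shape[1]), method="BFGS",
                       options={"gtol": 1e-12, "maxiter": 2000})
        np.testing.assert_allclose(fit.params["coef"].to_numpy(), res.x,
                                   atol=1e-5)

    def test_eq4_reports_tier_difference(self, rng):
        n = 3000
        group = rng.integers(0, 3, n)  # 0 background, 1 tier1, 2 tier2
        p = np.choose(group, [0.15, 0.45, 0.3])
        df = pd.DataFrame({
            "overlap": (rng.random(n) < p).astype(float),
            "tss_dist_signed": rng.uniform(-5e5, 5e5, n),
            "expression": rng.standard_normal(n),
            "is_tier1": (group == 1).astype(float),
            "is_tier2": (group == 2).astype(float)})
        df["tss_dist_abs"] = df["tss_dist_signed"].abs()
        fit = fit_enrichment("eq4", df)
        assert fit.coef("is_tier1") > fit.coef("is_tier2") > 0
        assert fit.extras["tier_diff"]["p"] < 0.05

    def test_unknown_model_and_nonbinary_outcome(self, rng):
        with pytest.raises(ValueError):
            fit_enrichment("eq9", pd.DataFrame())
        df = self._eq2_frame(rng, n=100)
        df.loc[0, "overlap"] = 0.5
        with pytest.raises(ValueError, match="binary"):
            fit_enrichment("eq2", df)
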