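"""Genotype QC, the fast correlation-QTL scan, and QTL annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cilp
from cilp import CovariateTable, GenotypeMatrix, NormalizationMode, StratumLabels, TraitMatrix
from conftest import naive_ols_pvalue


def exact_hwe_pvalue(n0, n1, n2):
    """Exact Hardy-Weinberg test (enumeration over heterozygote counts),
    independent oracle for the chi-square filter."""
    from math import lgamma

    n = n0 + n1 + n2
    n_rare = min(2 * n0 + n1, 2 * n2 + n1)

    def log_prob(het):
        hom_rare = (n_rare - het) // 2
        hom_common = n - het - hom_rare
        return (
            lgamma(n + 1)
            - lgamma(hom_rare + 1)
            - lgamma(het + 1)
            - lgamma(hom_common + 1)
            + het * np.log(2)
            + lgamma(n_rare + 1)
            + lgamma(2 * n - n_rare + 1)
            - lgamma(2 * n + 1)
        )

    hets = [h for h in range(n_rare % 2, n_rare + 1, 2)]
    logs = np.array([log_prob(h) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[hets.index(n1)]
    return probs[probs <= p_obs + 1e-12].sum()


class TestHwe:
    def test_perfect_hwe(self):
        assert cilp.hwe_test(25, 50, 25) == pytest.approx(1.0)

    def test_heterozygote_deficit_fails_filter(self):
        assert cilp.hwe_test(50, 0, 50) < 1e-6

    def test_monotone_in_sample_size(self):
        assert cilp.hwe_test(500, 0, 500) < cilp.hwe_test(50, 0, 50)

    def test_monomorphic_convention(self):
        assert cilp.hwe_test(100, 0, 0) == 1.0

    @pytest.mark.parametrize("counts", [(40, 20, 40), (10, 40, 10), (30, 45, 25)])
    def test_agrees_with_exact_oracle_on_filter_decision(self, counts):
        """Chi-square and exact test agree on which side of 1e-6 a SNP falls
        and correlate strongly in magnitude."""
        chi_p = cilp.hwe_test(*counts)
        exact_p = exact_hwe_pvalue(*counts)
        assert (chi_p < 1e-6) == (exact_p < 1e-6)
        if exact_p > 1e-12:
            assert abs(np.log10(chi_p) - np.log10(exact_p)) < 1.0


def _geno(data, positions=None, samples=None):
    idx = samples or [f"s{i}" for i in range(len(next(iter(data.values()))))]
    return GenotypeMatrix(pd.DataFrame(data, index=idx, dtype=float), positions)


class TestLdPrune:
    def test_duplicate_snp_dropped(self, rng):
        g = rng.binomial(2, 0.4, 100).astype(float)
        pos = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [1000, 1001]},
                           index=["s1", "s2"])
        gm = _geno({"s1": g, "s2": g}, pos)
        kept, pruned = cilp.ld_prune(gm)
        assert kept == ["s1"]
        assert pruned["s2"][0] == "s1" and pruned["s2"][1] == pytest.approx(1.0)

    def test_independent_snps_rarely_pruned(self, rng):
        n_snp = 60
        data = {f"v{j}": rng.binomial(2, 0.3, 1000).astype(float) for j in range(n_snp)}
        pos = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(n_snp) * 100 + 1}, index=list(data)
        )
        gm = _geno(data, pos)
        kept, pruned = cilp.ld_prune(gm)
        assert len(pruned) == 0

    def test_distant_snps_never_pruned(self, rng):
        g = rng.binomial(2, 0.4, 50).astype(float)
        pos = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [1, 60_001]},
                           index=["a", "b"])
        gm = _geno({"a": g, "b": g}, pos)
        kept, _ = cilp.ld_prune(gm, window_bp=50_000)
        assert kept == ["a", "b"]

    def test_missing_positions_error(self, rng):
        gm = _geno({"a": rng.binomial(2, 0.4, 50).astype(float)})
        with pytest.raises(cilp.CilpError, match="position"):
            cilp.ld_prune(gm)


class TestSnpQc:
    def test_filters_applied_and_consistent(self, rng):
        n = 400
        good = rng.binomial(2, 0.4, n).astype(float)
        rare = rng.binomial(2, 0.02, n).astype(float)
        bad_hwe = np.array([0.0, 2.0] * (n // 2))
        pos = pd.DataFrame(
            {"chrom": "chr1", "pos": [1, 200_000, 400_000]},
            index=["good", "rare", "badhwe"],
        )
        gm = _geno({"good": good, "rare": rare, "badhwe": bad_hwe}, pos)
        reports = {r.snp_id: r for r in cilp.snp_qc(gm)}
        assert reports["good"].passed
        assert not reports["rare"].passed
        assert not reports["badhwe"].passed
        for r in reports.values():
            marginal = (
                r.maf > 0.05 and r.hom_minor_fraction > 0.05 and r.hwe_p > 1e-6
            )
            assert r.passed == (marginal and not r.pruned_by_ld)

    def test_qc_idempotent(self, qtl_cohort):
        gm = qtl_cohort.genotypes
        first = cilp.snp_qc(gm)
        passed = [r.snp_id for r in first if r.passed]
        gm2 = GenotypeMatrix(gm.data[passed], gm.positions)
        second = cilp.snp_qc(gm2)
        assert [r.snp_id for r in second if r.passed] == passed


class TestSelectTopFeatures:
    def test_planted_associations_rank_first(self, rng):
        n, m = 500, 30
        idx = [f"s{i}" for i in range(n)]
        target = rng.standard_normal(n)
        vals = rng.standard_normal((n, m))
        vals[:, :5] += 0.5 * target[:, None]
        traits = TraitMatrix(
            pd.DataFrame(vals, index=idx, columns=[f"t{j:02d}" for j in range(m)])
        )
        top = cilp.select_top_features(traits, target, k=5)
        assert set(top) == {f"t{j:02d}" for j in range(5)}

    def test_k_equals_all_returns_everything(self, trait_frame, rng):
        target = rng.standard_normal(trait_frame.n_samples)
        out = cilp.select_top_features(trait_frame, target, k=5)
        assert sorted(out) == sorted(trait_frame.trait_ids)

    def test_permuted_target_uncorrelated_ranking(self, rng):
        n, m = 400, 40
        idx = [f"s{i}" for i in range(n)]
        target = rng.standard_normal(n)
        vals = rng.standard_normal((n, m))
        vals[:, :10] += 0.5 * target[:, None]
        traits = TraitMatrix(
            pd.DataFrame(vals, index=idx, columns=[f"t{j:02d}" for j in range(m)])
        )
        rhos = []
        for seed in range(8):
            perm = np.random.default_rng(seed).permutation(target)
            top = cilp.select_top_features(traits, perm, k=m)
            ranks = {t: i for i, t in enumerate(top)}
            planted = np.array([ranks[f"t{j:02d}"] for j in range(10)])
            other = np.array([ranks[f"t{j:02d}"] for j in range(10, m)])
            labels = np.r_[np.ones(10), np.zeros(m - 10)]
            rho = stats.spearmanr(np.r_[planted, other], labels).statistic
            rhos.append(rho)
        assert abs(np.mean(rhos)) < 0.1

    def test_gene_map_collapses_probes(self, rng):
        n = 200
        idx = [f"s{i}" for i in range(n)]
        target = rng.standard_normal(n)
        vals = np.column_stack(
            [target + 0.1 * rng.standard_normal(n),
             target + 0.2 * rng.standard_normal(n),
             rng.standard_normal(n)]
        )
        traits = TraitMatrix(pd.DataFrame(vals, index=idx, columns=["p1", "p2", "p3"]))
        gene_map = pd.Series({"p1": "G1", "p2": "G1", "p3": "G2"})
        top = cilp.select_top_features(traits, target, k=2, gene_map=gene_map)
        assert top == ["p1", "p3"]  # best probe per gene, two unique genes


class TestScan:
    def test_fast_path_matches_naive_ols(self, rng):
        n, n_snp, n_trait = 150, 20, 5
        idx = [f"s{i}" for i in range(n)]
        traits = TraitMatrix(
            pd.DataFrame(rng.standard_normal((n, n_trait)), index=idx,
                         columns=[f"t{j}" for j in range(n_trait)])
        )
        cov = CovariateTable(
            pd.DataFrame({"age": rng.normal(size=n), "sex": rng.binomial(1, 0.5, n)},
                         index=idx)
        )
        scaled = cilp.residualize(traits, cov)
        prod = cilp.pairwise_products(
            scaled, cilp.all_pairs(scaled.trait_ids),
            NormalizationMode.residualize_then_scale,
        )
        gm = GenotypeMatrix(
            pd.DataFrame(
                rng.binomial(2, 0.3, (n, n_snp)).astype(float),
                index=idx, columns=[f"v{j}" for j in range(n_snp)],
            )
        )
        hits = cilp.scan_correlation_qtl(prod, gm, cov)
        assert len(hits) == n_snp * prod.n_pairs
        X = cov.design_matrix().to_numpy(float)
        worst = 0.0
        for h in hits:
            g = gm.data[h.snp_id].to_numpy()
            y = prod.data.to_numpy()[:, prod.pair_index.index(h.pair)]
            beta, p = naive_ols_pvalue(y, np.column_stack([X, g]))
            worst = max(worst, abs(p - h.p))
            assert abs(beta - h.beta) < 1e-10
        assert worst < 1e-8

    def test_planted_qtl_recovered_with_sign(self, qtl_cohort):
        co = qtl_cohort
        scaled = cilp.residualize(co.traits, co.covariates)
        prod = cilp.pairwise_products(
            scaled, cilp.all_pairs(co.traits.trait_ids),
            NormalizationMode.residualize_then_scale,
        )
        hits = cilp.scan_correlation_qtl(prod, co.genotypes, co.covariates)
        planted = {(q["snp"], tuple(q["pair"])) for q in co.manifest["planted_qtls"]}
        bonf = {
            (h.snp_id, h.pair): h for h in hits if h.p < 0.05 / len(hits)
        }
        recovered = planted & set(bonf)
        assert len(recovered) == len(planted)
        assert all(bonf[k].beta > 0 for k in recovered)

    def test_null_genotypes_yield_no_fdr_hits(self, rng):
        n = 300
        idx = [f"s{i}" for i in range(n)]
        traits = TraitMatrix(
            pd.DataFrame(rng.standard_normal((n, 6)), index=idx,
                         columns=[f"t{j}" for j in range(6)])
        )
        scaled = cilp.residualize(traits, CovariateTable.empty(idx))
        prod = cilp.pairwise_products(
            scaled, cilp.all_pairs(scaled.trait_ids),
            NormalizationMode.residualize_then_scale,
        )
        gm = GenotypeMatrix(
            pd.DataFrame(rng.binomial(2, 0.4, (n, 30)).astype(float), index=idx,
                         columns=[f"v{j}" for j in range(30)])
        )
        hits = cilp.scan_correlation_qtl(prod, gm)
        assert sum(h.q < 0.10 for h in hits) == 0

    def test_mean_imputation_close_to_dropping_missing(self, rng):
        n = 500
        idx = [f"s{i}" for i in range(n)]
        g = rng.binomial(2, 0.4, n).astype(float)
        traits = TraitMatrix(
            pd.DataFrame(rng.standard_normal((n, 2)), index=idx, columns=["a", "b"])
        )
        scaled = cilp.residualize(traits, CovariateTable.empty(idx))
        prod = cilp.pairwise_products(
            scaled, [("a", "b")], NormalizationMode.residualize_then_scale
        )
        g_miss = g.copy()
        drop = rng.choice(n, size=int(0.02 * n), replace=False)
        g_miss[drop] = np.nan
        gm = GenotypeMatrix(pd.DataFrame({"v": g_miss}, index=idx))
        h = cilp.scan_correlation_qtl(prod, gm)[0]
        keep = ~np.isnan(g_miss)
        _, p_drop = naive_ols_pvalue(
            prod.values[keep, 0], np.column_stack([np.ones(keep.sum()), g[keep]])
        )
        # mean imputation at 2% missingness barely perturbs the p-value
        assert abs(np.log10(h.p + 1e-300) - np.log10(p_drop + 1e-300)) < 0.5


class TestLocation:
    snp_pos = pd.DataFrame({"chrom": ["chr1", "chr3"]}, index=["v1", "v2"])
    gene_pos = pd.DataFrame(
        {"chrom": ["chr1", "chr2", "chr1"]}, index=["g1", "g2", "g3"]
    )

    def _qtl(self, snp, pair):
        return cilp.CorrelationQtl(snp, pair, 0.1, 0.05, 2.0, 0.04)

    def test_cis_one(self):
        assert cilp.classify_location(
            self._qtl("v1", ("g1", "g2")), self.snp_pos, self.gene_pos
        ) == "cis_one"

    def test_trans(self):
        assert cilp.classify_location(
            self._qtl("v2", ("g1", "g2")), self.snp_pos, self.gene_pos
        ) == "trans"

    def test_cis_both(self):
        assert cilp.classify_location(
            self._qtl("v1", ("g1", "g3")), self.snp_pos, self.gene_pos
        ) == "cis_both"

    def test_missing_annotation_flagged(self):
        assert cilp.classify_location(
            self._qtl("v9", ("g1", "g2")), self.snp_pos, self.gene_pos
        ) == "unclassified"


class TestVarQtl:
    def test_variance_effect_detected_mean_effect_calibrated(self):
        hits = 0
        eqtl_ps = []
        for seed in range(12):
            rng = np.random.default_rng(500 + seed)
            n = 800
            g = rng.binomial(2, 0.5, n).astype(float)
            y = rng.standard_normal(n) * np.sqrt(1 + 10 * g)
            if cilp.test_varqtl(y, g) < 1e-4:
                hits += 1
            eqtl_ps.append(cilp.test_eqtl(y, g))
        assert hits >= 11
        assert (np.array(eqtl_ps) < 0.05).mean() < 0.25

    def test_mean_effect_detected_variance_calibrated(self):
        eqtl_hits, var_ps = 0, []
        for seed in range(12):
            rng = np.random.default_rng(700 + seed)
            n = 800
            g = rng.binomial(2, 0.5, n).astype(float)
            y = 1.0 * g + rng.standard_normal(n)
            if cilp.test_eqtl(y, g) < 1e-4:
                eqtl_hits += 1
            var_ps.append(cilp.test_varqtl(y, g))
        assert eqtl_hits == 12
        assert (np.array(var_ps) < 0.05).mean() < 0.25

    def test_homoscedastic_null_uniform(self):
        rng = np.random.default_rng(9)
        pvals = []
        for _ in range(300):
            n = 250
            g = rng.binomial(2, 0.5, n).astype(float)
            pvals.append(cilp.test_varqtl(rng.standard_normal(n), g))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestReplication:
    def _mk(self, betas, ps):
        return [
            cilp.CorrelationQtl(f"v{i}", ("a", "b"), b, 0.1, b / 0.1, p)
            for i, (b, p) in enumerate(zip(betas, ps))
        ]

    def test_self_replication(self):
        qs = self._mk([0.5] * 30, [1e-10] * 30)
        out = cilp.replication_concordance(qs, qs)
        assert out["sign_agreement_fraction"] == 1.0
        assert out["binomial_p"] < 1e-6
        assert out["n_replicated_bonferroni"] == 30

    def test_sign_flip(self):
        qs = self._mk([0.5] * 10, [1e-8] * 10)
        flipped = self._mk([-0.5] * 10, [1e-8] * 10)
        out = cilp.replication_concordance(qs, flipped)
        assert out["sign_agreement_fraction"] == 0.0

    def test_two_independent_cohorts_agree(self):
        """Independent cohorts with the same planted correlation QTLs give
        concordant effect signs and within-candidate FDR replication."""
        n, n_qtl = 1200, 20
        config = cilp.ScenarioConfig(n=n, b=0.3)

        def cohort_scan(seed):
            rng = np.random.default_rng(seed)
            idx = [f"s{i}" for i in range(n)]
            out = []
            for k in range(n_qtl):
                g = cilp.simulate_genotypes(n, 0.5, rng)
                y1, y2 = cilp.simulate_pair(config, g, rng)
                traits = TraitMatrix(
                    pd.DataFrame({"a": y1, "b": y2}, index=idx)
                )
                scaled = cilp.residualize(traits, CovariateTable.empty(idx))
                prod = cilp.pairwise_products(
                    scaled, [("a", "b")], NormalizationMode.residualize_then_scale
                )
                r = cilp.test_products_lm(prod, g)[0]
                out.append(
                    cilp.CorrelationQtl(
                        f"v{k}", (f"g{k}a", f"g{k}b"), r.beta, r.se, r.stat, r.p
                    )
                )
            return out

        disc = cohort_scan(811)
        repl = cohort_scan(812)
        out = cilp.replication_concordance(disc, repl)
        assert out["sign_agreement_fraction"] > 0.9
        assert out["n_replicated_fdr"] >= int(0.8 * n_qtl)
        assert out["binomial_p"] < 1e-4

    def test_empty_intersection_rejected(self):
        a = self._mk([0.5], [0.01])
        b = [cilp.CorrelationQtl("other", ("x", "y"), 0.1, 0.1, 1.0, 0.5)]
        with pytest.raises(cilp.CilpError):
            cilp.replication_concordance(a, b)


class TestSharedEqtlFailureMode:
    def test_shared_eqtl_inflates_modified_mode_only(self):
        """A SNP that shifts the mean of BOTH genes (at skewed allele
        frequency) produces spurious correlation-QTL signal under the
        residualize-then-scale mode, while per-genotype-class z-scoring
        removes it.  This is a documented limitation of the scalable mode."""
        rng = np.random.default_rng(123)
        n = 3000
        idx = [f"s{i}" for i in range(n)]
        g = rng.binomial(2, 0.2, n).astype(float)
        y1 = 1.0 * g + rng.standard_normal(n)
        y2 = 1.0 * g + rng.standard_normal(n)
        traits = TraitMatrix(pd.DataFrame({"a": y1, "b": y2}, index=idx))
        # modified mode: residualize on covariates that do NOT include genotype
        scaled_mod = cilp.residualize(traits, CovariateTable.empty(idx))
        prod_mod = cilp.pairwise_products(
            scaled_mod, [("a", "b")], NormalizationMode.residualize_then_scale
        )
        p_mod = cilp.test_products_lm(prod_mod, g)[0].p
        # exact mode: z-score within genotype class
        strata = StratumLabels(pd.Series([f"g{int(v)}" for v in g], index=idx))
        scaled_exact = cilp.scale_within_strata(traits, strata)
        prod_exact = cilp.pairwise_products(scaled_exact, [("a", "b")])
        p_exact = cilp.test_products_lm(prod_exact, g)[0].p
        assert p_mod < 1e-4  # false positive under the scalable mode
        assert p_exact > 0.01  # exact mode stays calibrated

    def test_modes_concordant_without_shared_eqtl(self, rng):
        """On a clean two-group design the two normalization modes give
        nearly identical rankings of significance."""
        n = 600
        idx = [f"s{i}" for i in range(n)]
        status = rng.binomial(1, 0.5, n).astype(float)
        m = 8
        vals = rng.standard_normal((n, m))
        # plant a few correlation differences
        for j in range(0, 4, 2):
            rho = np.where(status == 1, 0.6, 0.1)
            z1 = vals[:, j]
            vals[:, j + 1] = rho * z1 + np.sqrt(1 - rho**2) * vals[:, j + 1]
        traits = TraitMatrix(
            pd.DataFrame(vals, index=idx, columns=[f"t{j}" for j in range(m)])
        )
        pairs = cilp.all_pairs(traits.trait_ids)
        strata = StratumLabels(
            pd.Series(np.where(status == 1, "case", "ctrl"), index=idx)
        )
        p_exact = [
            r.p
            for r in cilp.test_products_lm(
                cilp.pairwise_products(
                    cilp.scale_within_strata(traits, strata), pairs
                ),
                status,
            )
        ]
        p_mod = [
            r.p
            for r in cilp.test_products_lm(
                cilp.pairwise_products(
                    cilp.residualize(traits, CovariateTable.empty(idx)),
                    pairs,
                    NormalizationMode.residualize_then_scale,
                ),
                status,
            )
        ]
        rho = stats.spearmanr(-np.log10(p_exact), -np.log10(p_mod)).statistic
        assert rho > 0.95
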