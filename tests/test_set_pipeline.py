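import numpy as np
import pytest

from conftest import make_genotype_data
from lmmset.genio import EmptyDataError, SnpSet, encode_and_impute
from lmmset.set_pipeline import (RunConfig, build_confounder_factor,
                                 draw_permutations, permute_set_genotypes,
                                 run_set_tests, run_uncorrected_set_tests,
                                 select_confounder_snps,
                                 univariate_linreg_pvalues, write_results_tsv)
from lmmset.simulate import (SimConfig, make_sets, simulate_genotypes,
                             simulate_phenotype)


def confounded_dataset(seed=5, n=300, s=600, n_sets=25, set_size=4,
                       sigma_set2=0.0, causal_from_sets=False):
    cfg = SimConfig(n_individuals=n, n_snps=s, n_sets=n_sets,
                    set_size_fixed=set_size, sigma_set2=sigma_set2, seed=seed)
    data = simulate_genotypes(cfg)
    rng = np.random.default_rng(seed + 1)
    bg = [data.snps[j].snp_id for j in rng.choice(s, size=50, replace=False)]
    sets = make_sets(data, cfg, rng, avoid_ids=bg if causal_from_sets else ())
    causal = [sid for st in sets for sid in st.snp_ids] if causal_from_sets else []
    data.phenotype = simulate_phenotype(data, bg, causal, cfg, rng)
    return data, sets, bg


class TestSelectConfounders:
    def test_causal_snps_rank_highly(self):
        """SNPs with strong effects land near the top of the ranking."""
        hits = 0
        for rep in range(5):
            rng = np.random.default_rng(400 + rep)
            n, s = 400, 300
            X = rng.binomial(2, 0.3, size=(n, s)).astype(float)
            causal = rng.choice(s, size=20, replace=False)
            beta = rng.uniform(0.25, 0.5, size=20) * rng.choice([-1, 1], 20)
            y = X[:, causal] @ beta + rng.standard_normal(n)
            data = make_genotype_data(X, phenotype=y)
            top = select_confounder_snps(data, k=50)
            top_idx = {int(t[2:]) for t in top}
            hits += len(top_idx & set(causal)) >= 15
        assert hits >= 3

    def test_explicit_k_count_contract(self, small_cohort):
        data, _ = small_cohort
        data = data.subset()
        rng = np.random.default_rng(0)
        data.phenotype = rng.standard_normal(data.n)
        assert len(select_confounder_snps(data, k=310)) == 310

    def test_auto_prefers_small_k_without_signal(self):
        """Independent phenotype: predictive CV picks the smallest grid size."""
        wins = 0
        for rep in range(3):
            rng = np.random.default_rng(900 + rep)
            n, s = 150, 200
            X = rng.binomial(2, 0.3, size=(n, s)).astype(float)
            data = make_genotype_data(X, phenotype=rng.standard_normal(n))
            ids = select_confounder_snps(data, k="auto")
            wins += len(ids) <= 20
        assert wins >= 2

    def test_tiny_cohort_rejects_auto(self):
        rng = np.random.default_rng(1)
        X = rng.binomial(2, 0.3, size=(10, 30)).astype(float)
        data = make_genotype_data(X, phenotype=rng.standard_normal(10))
        with pytest.raises(ValueError, match="explicit k"):
            select_confounder_snps(data, k="auto")


class TestExclusion:
    def make_two_chrom_data(self):
        rng = np.random.default_rng(2)
        d1 = make_genotype_data(rng.binomial(2, 0.3, size=(50, 30)).astype(float))
        # chromosome 1 SNPs rs0..rs29 at 0.5 cM spacing: rs20 sits at 10.0 cM
        return d1

    def test_within_2cm_excluded(self):
        data = self.make_two_chrom_data()
        X = encode_and_impute(data)
        test_set = SnpSet("S", ("rs20",))  # at 10.0 cM
        # rs23 at 11.5 cM: |delta| = 1.5 < 2 -> excluded
        W = build_confounder_factor(data, ["rs23"], test_set, 2.0, X)
        assert W.k == 0

    def test_same_position_other_chromosome_retained(self):
        rng = np.random.default_rng(3)
        X = rng.binomial(2, 0.3, size=(50, 30)).astype(float)
        data = make_genotype_data(X[:, :15], chrom="1")
        data2 = make_genotype_data(X[:, 15:], chrom="2")
        # merge the two chromosomes into one dataset
        from lmmset.genio import GenotypeData, SnpRecord
        snps = data.snps + [
            SnpRecord(f"rx{j}", "2", r.position_bp, r.position_cm, "A", "B")
            for j, r in enumerate(data2.snps)]
        merged = GenotypeData(individuals=data.individuals, snps=snps,
                              dosage=np.hstack([data.dosage, data2.dosage]))
        test_set = SnpSet("S", ("rs10",))  # chr1, 5.0 cM
        W = build_confounder_factor(merged, ["rx10"], test_set, 2.0)
        assert W.k == 1  # chr2 SNP at same cM coordinate is retained

    def test_test_set_member_excluded(self):
        data = self.make_two_chrom_data()
        test_set = SnpSet("S", ("rs5",))
        W = build_confounder_factor(data, ["rs5", "rs29"], test_set, 2.0)
        assert W.k == 1  # rs5 dropped (member), rs29 at 14.5 cM kept


class TestPermutations:
    def test_identity_permutation_preserves_columns(self, rng):
        V = rng.standard_normal((20, 3))
        out = permute_set_genotypes(V, np.arange(20))
        np.testing.assert_array_equal(out, V)

    def test_joint_row_permutation_preserves_ld(self, rng):
        V = rng.standard_normal((30, 4))
        perm = rng.permutation(30)
        out = permute_set_genotypes(V, perm)
        np.testing.assert_allclose(out.T @ out, V.T @ V, atol=1e-10)

    def test_reversal_of_single_column(self, rng):
        V = rng.standard_normal((10, 1))
        out = permute_set_genotypes(V, np.arange(10)[::-1])
        np.testing.assert_array_equal(out[:, 0], V[::-1, 0])

    def test_invalid_permutation_rejected(self, rng):
        V = rng.standard_normal((10, 1))
        with pytest.raises(ValueError, match="permutation"):
            permute_set_genotypes(V, np.zeros(10, dtype=int))

    def test_distinct_seeds_distinct_sequences(self):
        p1 = draw_permutations(50, 3, seed=1)
        p2 = draw_permutations(50, 3, seed=2)
        assert any(not np.array_equal(a, b) for a, b in zip(p1, p2))

    def test_same_seed_reproducible(self):
        p1 = draw_permutations(50, 3, seed=9)
        p2 = draw_permutations(50, 3, seed=9)
        assert all(np.array_equal(a, b) for a, b in zip(p1, p2))


class TestRunSetTests:
    @pytest.fixture(scope="class")
    def null_run(self):
        data, sets, _ = confounded_dataset(seed=5)
        config = RunConfig(seed=11, k_confounder=30)
        run = run_set_tests(data, sets, config)
        return data, sets, config, run

    def test_permutation_fit_count_contract(self, null_run):
        """n_sets x n_permutations permutation fits, exactly."""
        data, sets, config, run = null_run
        n_usable = sum(1 for r in run.results if not r.degenerate)
        assert run.metadata["n_permutation_fits"] == \
            n_usable * config.n_permutations

    def test_results_sorted_and_consistent(self, null_run):
        _, sets, _, run = null_run
        ps = [r.p_value for r in run.results]
        assert ps == sorted(ps)
        assert len(run.results) == len(sets)
        for r in run.results:
            if r.lrt == 0.0:
                assert r.p_value == 1.0

    def test_determinism_byte_identical(self, null_run, tmp_path):
        data, sets, config, run = null_run
        write_results_tsv(run, tmp_path / "a.tsv")
        run2 = run_set_tests(data, sets, config)
        write_results_tsv(run2, tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == \
            (tmp_path / "b.tsv").read_bytes()

    def test_set_order_does_not_change_significance(self, null_run, rng):
        data, sets, config, run = null_run
        shuffled = list(sets)
        rng.shuffle(shuffled)
        run2 = run_set_tests(data, shuffled, config)
        sig1 = {r.set_id for r in run.results
                if r.p_value <= run.metadata["bonferroni_threshold"]}
        sig2 = {r.set_id for r in run2.results
                if r.p_value <= run2.metadata["bonferroni_threshold"]}
        assert sig1 == sig2

    def test_causal_set_attains_smallest_p(self):
        """One strongly causal set among null sets wins the ranking."""
        wins = 0
        for rep in range(3):
            data, sets, bg = confounded_dataset(seed=60 + rep, n=350, s=500,
                                                n_sets=20, causal_from_sets=False)
            # inject a strong effect into one set
            target = sets[0]
            X = encode_and_impute(data)
            idx = data.snp_index()
            cols = [idx[s] for s in target.snp_ids]
            rng = np.random.default_rng(rep)
            Z = (X[:, cols] - X[:, cols].mean(0)) / X[:, cols].std(0)
            data.phenotype = data.phenotype + \
                np.sqrt(0.3 / len(cols)) * Z @ rng.standard_normal(len(cols))
            run = run_set_tests(data, sets, RunConfig(seed=rep, k_confounder=30))
            wins += run.results[0].set_id == target.set_id
        assert wins >= 2

    def test_real_and_permutation_stats_exchangeable_under_null(self, null_run):
        """Global null: the unpermuted statistics and the permutation
        statistics come from the same distribution (rank-sum test)."""
        from scipy.stats import ranksums
        from lmmset.set_pipeline import permutation_statistics
        data, sets, config, run = null_run
        perm = permutation_statistics(data, sets, config, n_rounds=5)
        perm = perm[~np.isnan(perm)].ravel()
        real = np.array([r.lrt for r in run.results if not r.degenerate])
        assert ranksums(real, perm).pvalue > 0.01

    def test_too_few_permutation_statistics_aborts(self):
        data, sets, _ = confounded_dataset(seed=5, n_sets=25)
        config = RunConfig(seed=11, k_confounder=30, n_permutations=1)
        with pytest.raises(EmptyDataError, match="permutation"):
            run_set_tests(data, sets[:2], config)


class TestUncorrected:
    def test_uncorrected_inflates_on_confounded_data(self):
        """Structured null data: the uncorrected pipeline finds more small
        P-values than the corrected one."""
        data, sets, _ = confounded_dataset(seed=21, n=300, s=600, n_sets=30)
        config = RunConfig(seed=2, k_confounder=40)
        corrected = run_set_tests(data, sets, config)
        uncorr = run_uncorrected_set_tests(data, sets, config)
        n_small_c = sum(r.p_value < 0.05 for r in corrected.results)
        n_small_u = sum(r.p_value < 0.05 for r in uncorr.results)
        assert n_small_u >= n_small_c

    def test_all_degenerate_uncorrected_raises(self):
        rng = np.random.default_rng(0)
        X = rng.binomial(2, 0.4, size=(60, 5)).astype(float)
        X[:, 0] = 1.0  # constant column -> degenerate kernel
        data = make_genotype_data(X, phenotype=rng.standard_normal(60))
        sets = [SnpSet("S", ("rs0",))]
        with pytest.raises(EmptyDataError, match="degenerate"):
            run_uncorrected_set_tests(data, sets, RunConfig(seed=0))


def test_univariate_pvalues_match_statsmodels_ols(rng):
    """Vectorized ranking P-values agree with per-SNP OLS."""
    import statsmodels.api as sm
    n, s = 80, 10
    X = rng.binomial(2, 0.3, size=(n, s)).astype(float)
    y = rng.standard_normal(n) + 0.3 * X[:, 0]
    p_fast = univariate_linreg_pvalues(X, y)
    for j in range(s):
        ols = sm.OLS(y, sm.add_constant(X[:, j])).fit()
        assert p_fast[j] == pytest.approx(ols.pvalues[1], rel=1e-8)
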