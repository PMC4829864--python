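"""Continuous-trait model machinery: likelihoods, fits, contrasts, simulators."""

import io

import numpy as np
import pytest
from scipy import stats

from islandpcm import pcm, synthetic, treeio
from islandpcm.treeio import read_newick, vcv_array


def grid_argmax(fn, grid):
    vals = [fn(g) for g in grid]
    return grid[int(np.argmax(vals))]


class TestBmLoglik:
    def test_two_tip_closed_form(self, cherry):
        # bivariate standard normal at (0, 2) around mean 1:
        # -log(2 pi) - ((1)^2 + (1)^2)/2 = -2.83788
        assert pcm.bm_loglik(cherry, [0.0, 2.0], 1.0, 1.0) == pytest.approx(
            -2.8378770664093453, abs=1e-5
        )

    def test_constant_data_prefers_vanishing_rate(self, three_tip):
        x = np.full(3, 0.7)
        lls = [pcm.bm_loglik(three_tip, x, s2, 0.7) for s2 in (1.0, 0.1, 0.01, 1e-4)]
        assert np.all(np.diff(lls) > 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_mvn_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tree = synthetic.yule_tree(8, seed)
        x = rng.normal(size=8)
        sigma2, root = 1.7, 0.3
        got = pcm.bm_loglik(tree, x, sigma2, root)
        want = stats.multivariate_normal.logpdf(
            x, mean=np.full(8, root), cov=sigma2 * vcv_array(tree)
        )
        assert got == pytest.approx(want, abs=1e-8)


class TestFitBm1:
    def test_two_tip_hand_gls(self, cherry):
        fit = pcm.fit_bm1(cherry, [0.0, 2.0])
        assert fit.root_state == pytest.approx(1.0, abs=1e-10)
        assert fit.sigma2 == pytest.approx(1.0, abs=1e-10)

    def test_branch_scaling_invariance(self, fixture_tree, rng):
        x = rng.normal(size=fixture_tree.n_tips)
        f1 = pcm.fit_bm1(fixture_tree, x)
        scaled = treeio.Phylogeny(
            fixture_tree.parent, fixture_tree.branch_length * 4.0,
            fixture_tree.tip_labels,
        )
        f2 = pcm.fit_bm1(scaled, x)
        assert f2.sigma2 == pytest.approx(f1.sigma2 / 4.0, rel=1e-9)
        assert f2.logL == pytest.approx(f1.logL, rel=1e-9)

    def test_matches_grid_search_oracle(self):
        tree = synthetic.yule_tree(6, 11)
        rng = np.random.default_rng(5)
        x = rng.normal(size=6)
        fit = pcm.fit_bm1(tree, x)
        grid = np.linspace(max(fit.sigma2 - 0.5, 1e-3), fit.sigma2 + 0.5, 1001)
        best = grid_argmax(
            lambda s2: pcm.bm_loglik(tree, x, s2, fit.root_state), grid
        )
        assert abs(best - fit.sigma2) <= (grid[1] - grid[0])

    def test_single_tip_rejected(self):
        t = read_newick("(A:1,B:1);")
        with pytest.raises((ValueError, KeyError)):
            pcm.fit_bm1(t, [1.0])


class TestFitBms:
    def test_uniform_painting_collapses_to_bm1(self, fixture_tree, rng):
        x = rng.normal(size=fixture_tree.n_tips)
        segs = {
            v: [("c", float(fixture_tree.branch_length[v]))]
            for v in range(fixture_tree.n_nodes)
            if v != fixture_tree.root
        }
        p = treeio.RegimePainting(segments=segs, alphabet=("c",))
        fs = pcm.fit_bms(fixture_tree, p, x)
        f1 = pcm.fit_bm1(fixture_tree, x)
        assert fs.sigma2_by_regime["c"] == pytest.approx(f1.sigma2, rel=1e-6)
        assert fs.logL == pytest.approx(f1.logL, abs=1e-6)

    def test_star_tree_regimes_decompose_into_group_variances(self):
        # a star phylogeny with tips split between two fully-painted regimes
        # factorizes: each regime's ML rate is its group's ML variance
        n = 12
        newick = "(" + ",".join(f"s{i}:1.0" for i in range(n)) + ");"
        tree = read_newick(newick)
        group_a = {tree.label_index[f"s{i}"] for i in range(n // 2)}
        segs = {}
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            regime = "a" if v in group_a else "b"
            segs[v] = [(regime, float(tree.branch_length[v]))]
        p = treeio.RegimePainting(segments=segs, alphabet=("a", "b"))
        rng = np.random.default_rng(3)
        x = np.empty(n)
        ids_a = sorted(group_a)
        ids_b = sorted(set(range(n)) - group_a)
        x[ids_a] = rng.normal(0, 1, n // 2)
        x[ids_b] = rng.normal(0, 3, n // 2)
        fit = pcm.fit_bms(tree, p, x)
        # oracle: independent tips with common mean mu; the ML rate of each
        # regime is its group's mean squared deviation about mu
        mu = fit.root_state
        va = float(np.mean((x[ids_a] - mu) ** 2))
        vb = float(np.mean((x[ids_b] - mu) ** 2))
        assert fit.sigma2_by_regime["a"] == pytest.approx(va, rel=1e-4)
        assert fit.sigma2_by_regime["b"] == pytest.approx(vb, rel=1e-4)

    def test_absent_regime_named_in_error(self, fixture_tree, fixture_painting, rng):
        p = treeio.RegimePainting(
            segments=fixture_painting.segments,
            alphabet=fixture_painting.alphabet + ("ghost",),
        )
        x = rng.normal(size=fixture_tree.n_tips)
        with pytest.raises(ValueError, match="ghost"):
            pcm.fit_bms(fixture_tree, p, x)

    def test_nesting_beats_bm1(self, fixture_tree, fixture_painting):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.normal(size=fixture_tree.n_tips)
            fs = pcm.fit_bms(fixture_tree, fixture_painting, x)
            f1 = pcm.fit_bm1(fixture_tree, x)
            assert fs.logL >= f1.logL - 1e-6


class TestFitOu1:
    def test_bm_limit_at_tiny_alpha(self, fixture_tree, rng):
        x = rng.normal(size=fixture_tree.n_tips)
        f1 = pcm.fit_bm1(fixture_tree, x)
        ll = pcm.ou_loglik(fixture_tree, x, 1e-8, f1.sigma2, f1.root_state)
        assert ll == pytest.approx(f1.logL, abs=1e-4)

    def test_star_tree_stationary_diagonal(self):
        n = 6
        tree = read_newick("(" + ",".join(f"s{i}:1.0" for i in range(n)) + ");")
        from islandpcm.pcm import _ou_structure

        V = 2.0 * _ou_structure(tree, 1.0)
        # sigma^2/(2 alpha) (1 - e^{-2 alpha T}) with T=1
        assert np.allclose(np.diag(V), 1.0 - np.exp(-2.0), atol=1e-10)
        assert V[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_non_ultrametric_rejected(self):
        t = read_newick("(A:1,B:2);")
        with pytest.raises(ValueError, match="ultrametric"):
            pcm.fit_ou1(t, [0.0, 1.0])

    def test_theta_recovery_under_strong_pull(self):
        # OU with alpha=2 on depth-1 trees: theta recoverable within +-0.2
        reps = 30
        errs = []
        rng = np.random.default_rng(77)
        for r in range(reps):
            tree = synthetic.yule_tree(100, rng)
            cfg = synthetic.SimConfig(
                n_tips=100, seed=int(rng.integers(2**31)), n_reps=1,
                rates={"continent": 1.0}, ou_alpha=2.0, ou_theta=0.0,
                fixed_tree=tree,
            )
            bundle = synthetic.simulate_dataset(cfg)[0]
            fit = pcm.fit_ou1(tree, bundle.traits)
            errs.append(fit.theta)
        assert abs(np.median(errs)) < 0.2


class TestAicc:
    def test_worked_value(self):
        assert pcm.aicc(-10.0, 2, 48) == pytest.approx(24.26667, abs=1e-5)

    def test_zero_parameters_reduces_to_deviance(self):
        assert pcm.aicc(-10.0, 0, 48) == pytest.approx(20.0)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            pcm.aicc(-10.0, 2, 3)

    def test_ranking_invariant_to_loglik_shift(self):
        fits1 = [
            pcm.BMFit(1, 0, -10, 2, 48, pcm.aicc(-10, 2, 48)),
            pcm.BMFit(1, 0, -12, 2, 48, pcm.aicc(-12, 2, 48), model="BMX"),
        ]
        fits2 = [
            pcm.BMFit(1, 0, -5, 2, 48, pcm.aicc(-5, 2, 48)),
            pcm.BMFit(1, 0, -7, 2, 48, pcm.aicc(-7, 2, 48), model="BMX"),
        ]
        r1 = pcm.compare_models(fits1)["model"].tolist()
        r2 = pcm.compare_models(fits2)["model"].tolist()
        assert r1 == r2


class TestPic:
    def test_cherry_single_contrast(self, cherry):
        cs = pcm.pic(cherry, [0.0, 2.0])
        assert len(cs) == 1
        assert abs(cs.contrasts[0]) == pytest.approx(1.41421, abs=1e-5)

    def test_three_tip_hand_recursion(self, three_tip):
        cs = pcm.pic(three_tip, [0.0, 2.0, 4.0])
        by_height = dict(zip(np.round(cs.heights, 9), cs.contrasts))
        assert by_height[1.0] == pytest.approx(-1.41421, abs=1e-5)
        assert by_height[0.0] == pytest.approx(-1.60357, abs=1e-5)

    def test_count_is_n_minus_one(self, fixture_tree, rng):
        x = rng.normal(size=fixture_tree.n_tips)
        assert len(pcm.pic(fixture_tree, x)) == fixture_tree.n_tips - 1

    def test_zero_pooled_branch_raises(self):
        t = read_newick("((A:0,B:0):1,C:2);")
        with pytest.raises(ZeroDivisionError):
            pcm.pic(t, [0.0, 1.0, 2.0])

    @pytest.mark.parametrize("seed", range(4))
    def test_reml_and_ml_rate_relation(self, seed):
        # sum of squared contrasts equals the GLS quadratic form, hence
        # REML = q/(n-1) and ML = q/n exactly
        tree = synthetic.yule_tree(9, seed)
        x = np.random.default_rng(seed).normal(size=9)
        cs = pcm.pic(tree, x)
        reml = cs.reml_rate()
        ml = pcm.fit_bm1(tree, x).sigma2
        n = tree.n_tips
        assert ml == pytest.approx(reml * (n - 1) / n, rel=1e-9)

    def test_reml_rate_matches_grid_search(self):
        tree = synthetic.yule_tree(6, 2)
        x = np.random.default_rng(9).normal(size=6)
        reml = pcm.pic(tree, x).reml_rate()
        # restricted likelihood of sigma2: integrate out the mean (GLS),
        # logL_R(s2) = -((n-1)/2) log s2 - q/(2 s2) + const
        C = vcv_array(tree)
        Ci = np.linalg.inv(C)
        one = np.ones(6)
        mu = (one @ Ci @ x) / (one @ Ci @ one)
        q = (x - mu) @ Ci @ (x - mu)
        grid = np.linspace(max(reml - 0.3, 1e-3), reml + 0.3, 2001)
        best = grid_argmax(lambda s2: -(5 / 2) * np.log(s2) - q / (2 * s2), grid)
        assert abs(best - reml) <= grid[1] - grid[0]


class TestAsrBm:
    def test_cherry_root_is_gls_mean(self, cherry):
        anc = pcm.asr_bm(cherry, [0.0, 2.0])
        assert anc[cherry.root] == pytest.approx(1.0)

    def test_constant_trait_everywhere(self, fixture_tree):
        anc = pcm.asr_bm(fixture_tree, np.full(fixture_tree.n_tips, 3.3))
        assert np.allclose(list(anc.values()), 3.3)

    def test_matches_dense_conditional_expectation(self):
        tree = synthetic.yule_tree(6, 4)
        x = np.random.default_rng(8).normal(size=6)
        anc = pcm.asr_bm(tree, x)
        C = vcv_array(tree)
        Ci = np.linalg.inv(C)
        one = np.ones(6)
        mu = (one @ Ci @ x) / (one @ Ci @ one)
        shared = tree.mrca_heights()
        for v, val in anc.items():
            want = mu + shared[v, : tree.n_tips] @ Ci @ (x - mu)
            assert val == pytest.approx(want, abs=1e-8)


class TestPglsResiduals:
    def test_exact_linear_relation_gives_zero(self, fixture_tree, rng):
        x = rng.normal(size=fixture_tree.n_tips)
        res = pcm.pgls_residuals(fixture_tree, 2.0 * x, x)
        assert np.allclose(res.to_numpy(), 0.0, atol=1e-10)

    def test_star_tree_equals_ols(self):
        n = 10
        tree = read_newick("(" + ",".join(f"s{i}:1.0" for i in range(n)) + ");")
        rng = np.random.default_rng(2)
        x = rng.normal(size=n)
        y = 1.0 + 0.5 * x + rng.normal(size=n)
        res = pcm.pgls_residuals(tree, y, x)
        ols = y - np.polynomial.polynomial.polyvander(x, 1) @ np.linalg.lstsq(
            np.column_stack([np.ones(n), x]), y, rcond=None
        )[0]
        assert np.allclose(res.to_numpy(), ols, atol=1e-10)

    def test_shift_invariance(self, fixture_tree, rng):
        x = rng.normal(size=fixture_tree.n_tips)
        y = 0.3 * x + rng.normal(size=fixture_tree.n_tips)
        r1 = pcm.pgls_residuals(fixture_tree, y, x)
        r2 = pcm.pgls_residuals(fixture_tree, y + 5.0, x)
        assert np.allclose(r1.to_numpy(), r2.to_numpy(), atol=1e-10)

    def test_collinear_covariate_rejected(self, fixture_tree):
        with pytest.raises(ValueError, match="collinear"):
            pcm.pgls_residuals(
                fixture_tree,
                np.arange(fixture_tree.n_tips, dtype=float),
                np.ones(fixture_tree.n_tips),
            )


class TestSimulators:
    def test_zero_rate_constant(self, fixture_tree):
        sims = pcm.sim_bm(fixture_tree, sigma2=0.0, root_state=2.0, n_reps=3, seed=1)
        assert np.allclose(sims, 2.0)

    def test_cherry_moment_check(self, cherry):
        sims = pcm.sim_bm(cherry, sigma2=1.0, root_state=0.0, n_reps=2000, seed=42)
        var = sims.var(axis=0)
        cov = np.cov(sims.T)[0, 1]
        assert np.allclose(var, 1.0, atol=0.07)
        assert abs(cov) < 0.07

    def test_bms_simulation_matches_regime_partition(self, fixture_tree, fixture_painting):
        rates = {"continent": 1.0, "Socotra": 10.0, "AbdAlKuri": 10.0}
        sims = pcm.sim_bm(
            fixture_tree, painting=fixture_painting, rates=rates,
            root_state=0.0, n_reps=4000, seed=7,
        )
        mats = treeio.regime_vcv_arrays(fixture_tree, fixture_painting)
        expect = sum(rates[r] * m for r, m in mats.items())
        got = np.cov(sims.T, bias=True)
        # Monte-Carlo error on variances of scale ~1 at 4000 reps
        assert np.allclose(np.diag(got), np.diag(expect), atol=0.25)

    def test_mvbm_moments_and_psd_check(self, three_tip):
        R = np.array([[1.0, 0.8], [0.8, 1.0]])
        sims = pcm.sim_mvbm(three_tip, R, [0.0, 0.0], n_reps=4000, seed=3)
        tipC = sims[:, 2, :]  # tip C, depth 2, independent of A/B
        cov = np.cov(tipC.T)
        assert np.allclose(cov, 2.0 * R, atol=0.25)
        with pytest.raises(ValueError, match="positive definite"):
            pcm.sim_mvbm(three_tip, [[1.0, 2.0], [2.0, 1.0]], 0.0, n_reps=1, seed=0)

    def test_seed_reproducibility(self, fixture_tree, fixture_painting):
        kw = dict(painting=fixture_painting,
                  rates={"continent": 1, "Socotra": 2, "AbdAlKuri": 20},
                  root_state=0.0, n_reps=5)
        a = pcm.sim_bm(fixture_tree, seed=99, **kw)
        b = pcm.sim_bm(fixture_tree, seed=99, **kw)
        assert np.array_equal(a, b)


class TestEvolVcv:
    def test_single_trait_reduces_to_bm1_rate(self, fixture_tree, rng):
        x = rng.normal(size=fixture_tree.n_tips)
        R = pcm.evol_vcv(fixture_tree, x[:, None])
        assert R.iloc[0, 0] == pytest.approx(pcm.fit_bm1(fixture_tree, x).sigma2)

    def test_duplicated_trait_column_rank_one(self, fixture_tree, rng):
        x = rng.normal(size=fixture_tree.n_tips)
        R = pcm.evol_vcv(fixture_tree, np.column_stack([x, x])).to_numpy()
        assert R[0, 0] == pytest.approx(R[0, 1]) == pytest.approx(R[1, 1])

    def test_matches_contrast_cross_products(self):
        tree = synthetic.yule_tree(6, 6)
        rng = np.random.default_rng(10)
        X = rng.normal(size=(6, 2))
        R_ml = pcm.evol_vcv(tree, X).to_numpy()
        u1 = pcm.pic(tree, X[:, 0]).contrasts
        u2 = pcm.pic(tree, X[:, 1]).contrasts
        U = np.column_stack([u1, u2])
        R_reml = U.T @ U / (6 - 1)
        assert np.allclose(R_ml, R_reml * 5 / 6, atol=1e-6)

    def test_more_traits_than_species_rejected(self, three_tip):
        with pytest.raises(ValueError):
            pcm.evol_vcv(three_tip, np.zeros((3, 4)))


class TestTraitTable:
    def test_log10_at_ingestion(self):
        csv = "species,SVL,HL\nA,100,10\nB,10,1\n"
        tt = pcm.TraitTable.read_csv(io.StringIO(csv))
        assert tt.scale == "log10"
        assert tt.data.loc["A", "svl"] == pytest.approx(2.0)
        assert tt.data.loc["B", "hl"] == pytest.approx(0.0)

    def test_raw_scale_flag(self):
        csv = "species,svl\nA,1.5\n"
        tt = pcm.TraitTable.read_csv(io.StringIO(csv), log10=False)
        assert tt.scale == "raw"
        assert tt.data.loc["A", "svl"] == 1.5

    def test_missing_values_dropped_per_analysis(self):
        csv = "species,svl,hl\nA,10,\nB,20,2\nC,30,3\n"
        tt = pcm.TraitTable.read_csv(io.StringIO(csv))
        assert list(tt.column("hl").index) == ["B", "C"]
        assert list(tt.column("svl").index) == ["A", "B", "C"]
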