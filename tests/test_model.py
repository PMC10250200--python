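import numpy as np
import pandas as pd
import pytest

from phyloensemble.design import DesignError, ModelSpec, PriorSpec, build_design
from phyloensemble.model import (
    PhyloMixedModel,
    PosteriorSamples,
    compute_dic,
    compute_r2,
    fit_pmm,
    gls_oracle,
)
from phyloensemble.simulate import simulate_yule_tree
from phyloensemble.trees import phylo_covariance


def _gaussian_df(n, rng, p=2):
    X = rng.normal(size=(n, p))
    beta = rng.uniform(0.5, 2.0, p) * rng.choice([-1, 1], p)
    b0 = rng.uniform(0.5, 2.0)
    y = b0 + X @ beta + rng.normal(0, 1, n)
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
    df["const"] = "c"
    df["y"] = y
    return df


def _gaussian_spec(p=2):
    return ModelSpec(
        "gaussian",
        "y",
        fixed_terms=[{"factor": "const"}]
        + [{"covariate": f"x{i}", "transform": "none"} for i in range(p)],
    )


class TestGlsOracle:
    def test_identity_covariance_is_ols(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        y = rng.normal(size=20)
        coef, _ = gls_oracle(y, X, np.eye(20))
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(coef, ols)

    def test_intercept_only_mean(self):
        coef, _ = gls_oracle(np.array([1.0, 3.0]), np.ones((2, 1)), np.eye(2))
        assert coef[0] == pytest.approx(2.0)

    def test_nontrivial_covariance_matches_direct_evaluation(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(5), rng.normal(size=5)])
        y = rng.normal(size=5)
        A = rng.normal(size=(5, 5))
        V = A @ A.T + 5 * np.eye(5)
        coef, _ = gls_oracle(y, X, V)
        Vi = np.linalg.inv(V)
        direct = np.linalg.inv(X.T @ Vi @ X) @ X.T @ Vi @ y
        assert np.allclose(coef, direct, atol=1e-10)

    def test_singular_inputs_rejected(self):
        X = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(np.linalg.LinAlgError):
            gls_oracle(np.zeros(4), X, np.eye(4))
        with pytest.raises(np.linalg.LinAlgError):
            gls_oracle(np.zeros(4), np.ones((4, 1)), np.zeros((4, 4)))


class TestGaussianSampler:
    def test_constant_response_recovers_value(self):
        df = pd.DataFrame({"y": np.full(20, 5.0), "const": "c"})
        spec = ModelSpec("gaussian", "y", fixed_terms=[{"factor": "const"}])
        samples, _ = fit_pmm(df, spec, iterations=6000, burn_in=1000, thin=1, seed=0)
        from phyloensemble.summaries import posterior_mode

        assert abs(posterior_mode(samples.column("const[c]")) - 5.0) < 0.05

    def test_posterior_means_match_gls(self):
        rng = np.random.default_rng(2)
        df = _gaussian_df(30, rng)
        spec = _gaussian_spec()
        samples, _ = fit_pmm(df, spec, iterations=12000, burn_in=2000, thin=1, seed=3)
        X = np.column_stack(
            [np.ones(30), df.x0.to_numpy(), df.x1.to_numpy()]
        )
        coef, _ = gls_oracle(df.y.to_numpy(), X, np.eye(30))
        post = samples.draws[:, :3].mean(0)
        assert np.abs(post - coef).max() < 0.02

    def test_variance_draws_positive(self):
        rng = np.random.default_rng(4)
        df = _gaussian_df(25, rng)
        df["grp"] = list("abcde") * 5
        spec = ModelSpec(
            "gaussian", "y",
            fixed_terms=[{"factor": "const"}],
            random_terms=[{"group": "grp"}],
        )
        samples, _ = fit_pmm(df, spec, iterations=2000, burn_in=500, thin=1, seed=5)
        assert (samples.column("V[grp]") > 0).all()
        assert (samples.column("V[units]") > 0).all()
        assert np.isfinite(samples.draws).all()

    def test_chaining_restarts_from_state(self):
        rng = np.random.default_rng(6)
        df = _gaussian_df(20, rng)
        spec = _gaussian_spec()
        _, state = fit_pmm(df, spec, iterations=500, burn_in=100, thin=1, seed=7)
        samples2, _ = fit_pmm(
            df, spec, iterations=200, burn_in=0, thin=1, seed=8, initial=state
        )
        assert samples2.n_draws == 200


class TestDesignErrors:
    def test_rank_deficient_lists_aliased_columns(self):
        df = pd.DataFrame({"y": np.zeros(8), "a": list("xxyy") * 2,
                           "b": list("xxyy") * 2})
        spec = ModelSpec("gaussian", "y",
                         fixed_terms=[{"factor": "a"}, {"factor": "b"}])
        with pytest.raises(DesignError, match="aliased"):
            build_design(df, spec)

    def test_non_pd_covariance_reports_eigenvalue(self):
        df = pd.DataFrame(
            {"y": np.zeros(4), "const": "c", "sp": ["A", "B", "A", "B"]}
        )
        spec = ModelSpec(
            "gaussian", "y", fixed_terms=[{"factor": "const"}],
            random_terms=[{"group": "sp", "covariance": "phylo"}],
        )
        from phyloensemble.trees import PhyloCovariance

        bad = PhyloCovariance(["A", "B"], np.array([[1.0, 1.0], [1.0, 1.0]]))
        with pytest.raises(np.linalg.LinAlgError, match="eigenvalue"):
            fit_pmm(df, spec, covariances={"phylo": bad}, iterations=10,
                    burn_in=1, thin=1)

    def test_binomial_requires_integer_pairs(self):
        df = pd.DataFrame({"s": [0.5, 1.2], "f": [1.0, 2.0], "const": "c"})
        spec = ModelSpec("binomial-logit", ("s", "f"),
                         fixed_terms=[{"factor": "const"}])
        with pytest.raises(ValueError, match="integer"):
            fit_pmm(df, spec, iterations=10, burn_in=1, thin=1)


class TestBinomialSampler:
    def test_liability_acceptance_reasonable_on_binary_data(self):
        # single-trial rows: the adapted random-walk should settle in a sane
        # acceptance window rather than degenerate
        rng = np.random.default_rng(9)
        n = 60
        s = rng.integers(0, 2, n)
        df = pd.DataFrame({"s": s, "f": 1 - s, "const": "c"})
        spec = ModelSpec("binomial-logit", ("s", "f"),
                         fixed_terms=[{"factor": "const"}])
        # binary data cannot identify the residual variance; fix it to one
        samples, _ = fit_pmm(df, spec, iterations=3000, burn_in=1500, thin=1,
                             seed=10, fix_residual=True)
        assert 0.1 < samples.extras["acceptance"] < 0.6

    def test_recovers_logit_on_large_counts(self):
        rng = np.random.default_rng(11)
        n = 50
        p = 0.2
        s = rng.binomial(400, p, n)
        df = pd.DataFrame({"s": s, "f": 400 - s, "const": "c"})
        spec = ModelSpec("binomial-logit", ("s", "f"),
                         fixed_terms=[{"factor": "const"}])
        samples, _ = fit_pmm(df, spec, iterations=6000, burn_in=2000, thin=2,
                             seed=12)
        est = samples.column("const[c]").mean()
        assert est == pytest.approx(np.log(p / (1 - p)), abs=0.3)


class TestDic:
    def test_degenerate_posterior_has_zero_pd(self):
        y = np.array([1.0, 2.0, 3.0])
        df = pd.DataFrame({"y": y, "const": "c"})
        spec = ModelSpec("gaussian", "y", fixed_terms=[{"factor": "const"}])
        eta = np.full(3, 2.0)
        dev = float(3 * np.log(2 * np.pi * 1.0) + ((y - eta) ** 2).sum())
        samples = PosteriorSamples(
            names=["const[c]", "V[units]"],
            draws=np.tile([2.0, 1.0], (50, 1)),
            meta=pd.DataFrame({"tree_index": [0] * 50, "iteration": range(50)}),
            extras={"mean_eta": eta, "deviance": np.full(50, dev)},
        )
        assert compute_dic(samples, df, spec) == pytest.approx(dev)

    def test_binomial_family_unsupported(self):
        df = pd.DataFrame({"s": [1], "f": [1]})
        spec = ModelSpec("binomial-logit", ("s", "f"))
        samples = PosteriorSamples(
            names=["a"], draws=np.ones((2, 1)),
            meta=pd.DataFrame({"tree_index": [0, 0], "iteration": [0, 1]}),
        )
        with pytest.raises(ValueError, match="gaussian"):
            compute_dic(samples, df, spec)

    def test_noise_covariate_adds_about_one_effective_parameter(self):
        rng = np.random.default_rng(13)
        n = 2000
        df = _gaussian_df(n, rng, p=1)
        df["noise"] = rng.normal(size=n)
        spec_small = _gaussian_spec(p=1)
        spec_big = ModelSpec(
            "gaussian", "y",
            fixed_terms=spec_small.fixed_terms
            + [{"covariate": "noise", "transform": "none"}],
        )
        def pd_of(spec):
            samples, _ = fit_pmm(df, spec, iterations=6000, burn_in=1000,
                                 thin=1, seed=14)
            dic = compute_dic(samples, df, spec)
            dbar = float(np.mean(samples.extras["deviance"]))
            return dic - dbar
        delta = pd_of(spec_big) - pd_of(spec_small)
        assert 0.5 < delta < 1.5

    def test_smaller_true_model_usually_wins(self):
        wins = 0
        reps = 20
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            n = 60
            df = _gaussian_df(n, rng, p=1)
            df["noise"] = rng.normal(size=n)
            small = _gaussian_spec(p=1)
            big = ModelSpec(
                "gaussian", "y",
                fixed_terms=small.fixed_terms
                + [{"covariate": "noise", "transform": "none"}],
            )
            dics = []
            for spec in (small, big):
                samples, _ = fit_pmm(df, spec, iterations=3000, burn_in=500,
                                     thin=1, seed=200 + rep)
                dics.append(compute_dic(samples, df, spec))
            if dics[0] < dics[1]:
                wins += 1
        assert wins >= 13  # ~80% expected


class TestR2:
    def _mk(self, eta, y):
        df = pd.DataFrame({"y": y, "const": "c"})
        spec = ModelSpec("gaussian", "y", fixed_terms=[{"factor": "const"}])
        samples = PosteriorSamples(
            names=["const[c]", "V[units]"], draws=np.ones((10, 2)),
            meta=pd.DataFrame({"tree_index": [0] * 10, "iteration": range(10)}),
            extras={"mean_eta": np.asarray(eta, float)},
        )
        return samples, df, spec

    def test_perfect_predictions(self):
        y = np.arange(5.0)
        samples, df, spec = self._mk(y, y)
        assert compute_r2(samples, df, spec) == pytest.approx(1.0)

    def test_independent_predictions_near_zero(self):
        rng = np.random.default_rng(15)
        y = rng.normal(size=10000)
        samples, df, spec = self._mk(rng.normal(size=10000), y)
        assert compute_r2(samples, df, spec) < 0.01

    def test_constant_predictions_return_zero_with_warning(self):
        y = np.arange(5.0)
        samples, df, spec = self._mk(np.zeros(5), y)
        with pytest.warns(UserWarning, match="zero-variance"):
            assert compute_r2(samples, df, spec) == 0.0


class TestModelObject:
    def test_summary_and_diagnostics(self):
        rng = np.random.default_rng(16)
        df = _gaussian_df(40, rng)
        model = PhyloMixedModel(df, _gaussian_spec())
        res = model.fit(iterations=3000, burn_in=500, thin=2, seed=17)
        summ = res.summary()
        assert set(summ.columns) >= {"term", "post_mode", "hpd_low", "hpd_high",
                                     "pMCMC"}
        assert len(summ) == len(res.samples.names)
        assert 0 <= res.r2() <= 1
        assert np.isfinite(res.dic())

    def test_phylo_random_term_fit(self, study_tree):
        rng = np.random.default_rng(18)
        cov = phylo_covariance(study_tree, as_correlation=True)
        sp = study_tree.tip_labels
        df = pd.DataFrame({
            "y": rng.normal(size=len(sp)), "const": "c", "species": sp,
        })
        spec = ModelSpec(
            "gaussian", "y", fixed_terms=[{"factor": "const"}],
            random_terms=[{"group": "species", "covariance": "phylo"}],
        )
        model = PhyloMixedModel(df, spec, covariances={"phylo": cov})
        res = model.fit(iterations=1500, burn_in=500, thin=1, seed=19)
        assert (res.samples.column("V[phylo.species]") > 0).all()

    def test_posterior_csv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(20)
        df = _gaussian_df(20, rng)
        samples, _ = fit_pmm(df, _gaussian_spec(), iterations=300, burn_in=100,
                             thin=1, seed=21)
        path = tmp_path / "post.csv"
        samples.to_csv(path)
        back = PosteriorSamples.from_csv(path)
        assert back.names == samples.names
        assert np.allclose(back.draws, samples.draws)
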