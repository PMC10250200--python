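import numpy as np
import pytest

from phyloensemble.simulate import (
    FactorialDesign,
    SimulationParams,
    jitter_tree_ensemble,
    simulate_experiment,
    simulate_lake_data,
    simulate_yule_tree,
)
from phyloensemble.trees import phylo_covariance


class TestYule:
    def test_tip_count_and_ultrametricity(self):
        t = simulate_yule_tree(5, seed=0)
        assert t.n_tips == 5
        assert t.is_ultrametric()

    def test_determinism(self):
        a = simulate_yule_tree(7, seed=42).to_newick()
        b = simulate_yule_tree(7, seed=42).to_newick()
        assert a == b

    def test_rejects_tiny_trees(self):
        with pytest.raises(ValueError):
            simulate_yule_tree(1)

    def test_mean_depth_matches_yule_expectation(self):
        # E[depth] = sum_{k=2..n} 1/(k * birth_rate); Monte-Carlo check and
        # halving under a doubled birth rate
        n, reps = 6, 400
        expected = sum(1.0 / k for k in range(2, n + 1))
        for lam in (1.0, 2.0):
            depths = [
                simulate_yule_tree(n, birth_rate=lam, seed=int(1000 * lam) + i).depth
                for i in range(reps)
            ]
            assert np.mean(depths) == pytest.approx(expected / lam, abs=0.1 / lam)


class TestJitter:
    def test_zero_noise_gives_copies(self):
        t = simulate_yule_tree(6, seed=1)
        ens = jitter_tree_ensemble(t, 3, 0.0, seed=2)
        assert len(ens) == 3
        assert {x.to_newick() for x in ens} == {t.to_newick()}

    def test_seeded_reproducibility(self):
        t = simulate_yule_tree(6, seed=1)
        a = [x.to_newick() for x in jitter_tree_ensemble(t, 4, 0.1, seed=3)]
        b = [x.to_newick() for x in jitter_tree_ensemble(t, 4, 0.1, seed=3)]
        assert a == b

    def test_negative_noise_rejected(self):
        t = simulate_yule_tree(4, seed=1)
        with pytest.raises(ValueError):
            jitter_tree_ensemble(t, 2, -0.1)

    def test_trees_stay_ultrametric(self):
        t = simulate_yule_tree(12, seed=4)
        for x in jitter_tree_ensemble(t, 10, 0.2, seed=5):
            assert x.is_ultrametric()

    def test_mean_covariance_near_base_for_small_noise(self):
        t = simulate_yule_tree(8, seed=6)
        base = phylo_covariance(t, as_correlation=True)
        mats = [
            phylo_covariance(x, as_correlation=True).reorder(base.labels).matrix
            for x in jitter_tree_ensemble(t, 60, 0.02, seed=7)
        ]
        mean = np.mean(mats, axis=0)
        assert np.abs(mean - base.matrix).max() < 0.05


class TestExperiment:
    def test_counts_sum_to_particle_total(self, experiment):
        tab = experiment.table
        total = tab.n_single + tab.n_palmelloid_cells + tab.n_group_cells
        assert (total == 400).all()

    def test_study_scale_row_count(self, experiment):
        # 35 strains x 8 treatments
        assert len(experiment.table) == 280
        assert experiment.table.strain.nunique() == 35
        assert experiment.table.lake.nunique() <= 10

    def test_determinism(self, study_tree):
        p = SimulationParams(seed=5)
        a = simulate_experiment(study_tree, params=p).table
        b = simulate_experiment(study_tree, params=p).table
        assert a.equals(b)

    def test_baseline_logit_matches_binomial_mean(self):
        # all effects and variances zero, group intercept -2: the mean group
        # fraction must sit at logistic(-2) within Monte-Carlo error
        tree = simulate_yule_tree(10, seed=8)
        params = SimulationParams(
            n_strains=125, n_lakes=2,
            fixed_effects={"group": {"intercept": -2.0}, "palmelloid": {},
                           "ecm": {}, "sgr": {}},
            V_phylo=0, V_lake=0, V_strain=0, V_residual=0,
            sgr_V_phylo=0, sgr_V_lake=0, sgr_V_strain=0, sgr_V_residual=0,
            seed=9,
        )
        exp = simulate_experiment(tree, params=params)
        assert len(exp.table) == 1000
        mean_prop = (exp.table.n_group_cells / 400).mean()
        assert mean_prop == pytest.approx(1 / (1 + np.exp(2)), abs=0.005)

    def test_invariants_over_random_parameter_draws(self):
        # counts non-negative and bounded, concentrations positive, for many
        # random parameter draws
        rng = np.random.default_rng(10)
        tree = simulate_yule_tree(5, seed=11)
        for rep in range(200):
            params = SimulationParams(
                n_strains=6,
                n_lakes=2,
                V_phylo=float(rng.uniform(0, 3)),
                V_lake=float(rng.uniform(0, 1)),
                V_strain=float(rng.uniform(0, 2)),
                V_residual=float(rng.uniform(0, 3)),
                seed=int(rng.integers(2**31)),
            )
            tab = simulate_experiment(tree, params=params).table
            counts = tab[["n_single", "n_palmelloid_cells", "n_group_cells"]]
            assert (counts >= 0).all().all()
            assert (counts.sum(axis=1) == 400).all()
            assert tab.ecm_single.between(0, 10).all()
            assert (tab.N_t0 > 0).all() and (tab.N_t1 > 0).all()

    def test_phylo_variance_creates_strain_clustering(self):
        # with V_phylo, V_strain > 0 the strain-level empirical logits must
        # show positive intraclass correlation in nearly all replicates
        from scipy.special import logit

        hits = 0
        reps = 60
        for rep in range(reps):
            tree = simulate_yule_tree(10, seed=300 + rep)
            params = SimulationParams(
                n_strains=20, n_lakes=2, V_phylo=1.0, V_strain=1.0,
                V_residual=0.5, seed=600 + rep,
                # moderate baseline, no treatment effects: clustering is then
                # observable on the empirical logit scale without saturation
                fixed_effects={"group": {"intercept": -1.0}, "palmelloid": {},
                               "ecm": {}, "sgr": {}},
            )
            tab = simulate_experiment(tree, params=params).table
            p = (tab.n_group_cells + 0.5) / 401
            y = logit(p)
            groups = tab.groupby("strain")["n_group_cells"].count()
            gm = y.groupby(tab.strain).mean()
            between = gm.var(ddof=1)
            within = y.groupby(tab.strain).var(ddof=1).mean()
            n_bar = groups.mean()
            icc = (between - within / n_bar) / (between + within * (1 - 1 / n_bar))
            if icc > 0:
                hits += 1
        assert hits >= int(0.95 * reps) - 1

    def test_fourth_class_behind_flag(self, study_tree):
        params = SimulationParams(seed=13, include_other_class=True)
        tab = simulate_experiment(study_tree, params=params).table
        assert "n_other" in tab.columns
        total = (
            tab.n_single + tab.n_palmelloid_cells + tab.n_group_cells + tab.n_other
        )
        assert (total == 400).all()

    def test_predator_density_design(self, study_tree):
        design = FactorialDesign.predator_density()
        params = SimulationParams(
            seed=14,
            fixed_effects={
                "group": {"intercept": -3, "predation:high": 1.0},
                "palmelloid": {"intercept": -2}, "ecm": {"intercept": 0},
                "sgr": {"intercept": 0.3, "predation:high": -0.1},
            },
        )
        tab = simulate_experiment(study_tree, design=design, params=params).table
        assert set(tab.predation) == {"none", "low", "high"}
        assert len(tab) == 35 * 3


class TestLake:
    def test_zero_effects_mean_half(self):
        tree = simulate_yule_tree(200, seed=15)
        params = SimulationParams(
            V_phylo=0, V_residual=0, seed=16,
        )
        lake = simulate_lake_data(
            tree, params=params,
            effects={"ecm": {"intercept": 0.0}, "multicellular": {"intercept": 0.0}},
        )
        tab = lake.table
        frac = tab.n_species_multicellular.sum() / (
            tab.n_species_multicellular + tab.n_species_unicellular
        ).sum()
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_determinism(self):
        tree = simulate_yule_tree(30, seed=17)
        p = SimulationParams(seed=18)
        a = simulate_lake_data(tree, params=p).table
        b = simulate_lake_data(tree, params=p).table
        assert a.equals(b)

    def test_ammonium_effect_sign_recovered(self):
        # positive ammonium slope on ECM recovered by a logistic fit of the
        # ECM species fractions in >= 95% of replicates
        import statsmodels.api as sm

        hits = 0
        reps = 60
        for rep in range(reps):
            tree = simulate_yule_tree(60, seed=700 + rep)
            params = SimulationParams(V_phylo=0.3, V_residual=0.3, seed=900 + rep)
            tab = simulate_lake_data(tree, params=params).table
            z = (tab.log_ammonium - tab.log_ammonium.mean()) / tab.log_ammonium.std()
            X = np.column_stack([np.ones(len(tab)), z])
            y = np.column_stack([tab.n_species_ecm, tab.n_species_no_ecm])
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            if fit.params[1] > 0:
                hits += 1
        assert hits >= int(0.95 * reps) - 1
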