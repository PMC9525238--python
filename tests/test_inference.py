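"""RJ-MCMC sampler, stepping-stone estimator and the clade orchestrator."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

import saltcross as sc
from saltcross.ctmc import RateModel, TreeLikelihood
from saltcross.inference import (
    ModelSpace,
    PriorSpec,
    SteppingStoneConfig,
    compare_models,
    sample_posterior,
    stepping_stone,
    subsample_tree_set,
)
from saltcross.synth import SimulationConfig


@pytest.fixture(scope="module")
def small_trees():
    at = sc.annotate(
        sc.read_tree("((a:0.5,b:0.5):0.5,(c:0.5,d:0.5):0.5);"),
        {"a": "marine", "b": "non_marine", "c": "marine", "d": "marine"},
    )
    return sc.TreeSet([at])


class TestPriorSpec:
    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(hyper_mean_bounds=(2.0, 1.0))
        with pytest.raises(ValueError):
            PriorSpec(fixed_mean=-1.0)

    def test_rate_density_is_exponential(self):
        p = PriorSpec()
        assert p.log_rate_density(0.7, 2.0) == pytest.approx(
            stats.expon(scale=2.0).logpdf(0.7)
        )


class TestCompareModels:
    def test_threshold_and_direction(self):
        c = compare_models(-100.0, -110.0)
        assert c.log_bayes_factor == pytest.approx(20.0)
        assert c.verdict == "favour heterogeneous"

    def test_equal_evidence(self):
        c = compare_models(-50.0, -50.0)
        assert c.log_bayes_factor == 0.0
        assert c.verdict == "no decisive preference"

    def test_antisymmetric_under_swap(self):
        a = compare_models(-90.0, -97.0)
        b = compare_models(-97.0, -90.0)
        assert a.log_bayes_factor == -b.log_bayes_factor

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            compare_models(float("nan"), -1.0)


class TestSampler:
    def test_same_seed_identical_trace(self, small_trees):
        a = sample_posterior(small_trees, gens_per_tree=400, seed=11)
        b = sample_posterior(small_trees, gens_per_tree=400, seed=11)
        assert a.draws.equals(b.draws)

    def test_different_seed_differs(self, small_trees):
        a = sample_posterior(small_trees, gens_per_tree=400, seed=11)
        b = sample_posterior(small_trees, gens_per_tree=400, seed=12)
        assert not a.draws.equals(b.draws)

    def test_prior_only_recovers_hyperprior_and_rates(self, small_trees):
        """With the likelihood switched off the chain samples the prior:
        m ~ Uniform(0,2) and q/m ~ Exp(1)."""
        post = sample_posterior(
            small_trees, gens_per_tree=60_000, burn_in=5_000,
            seed=9, power=0.0, thin=20,
        )
        m = post.draws["m"].to_numpy()
        q = post.draws["q_mn[background]"].to_numpy()
        assert stats.kstest(m, stats.uniform(0, 2).cdf).pvalue > 0.01
        assert stats.kstest(q / m, stats.expon.cdf).pvalue > 0.01
        # equal/unequal indicator near its 50/50 prior
        assert abs(post.p_equal() - 0.5) < 0.1

    def test_equal_space_keeps_rates_tied(self, small_trees):
        post = sample_posterior(
            small_trees, ModelSpace(rates="equal"), gens_per_tree=300, seed=3
        )
        r = post.rates()
        assert (r["q_mn"] == r["q_nm"]).all()

    def test_burn_in_validation(self, small_trees):
        with pytest.raises(ValueError, match="burn_in"):
            sample_posterior(small_trees, gens_per_tree=100, burn_in=100, seed=1)

    def test_tree_index_mixes_over_tree_set(self):
        t = sc.simulate_tree(SimulationConfig(num_tips=12, seed=21))
        at, _ = sc.simulate_history(t, RateModel(0.5, 0.5), seed=22)
        trees = sc.make_tree_set(at, n=5, jitter_sd=0.2, seed=23)
        post = sample_posterior(trees, gens_per_tree=300, seed=24)
        assert post.draws["tree"].nunique() > 1

    def test_cycle_mode_visits_trees_in_schedule(self):
        t = sc.simulate_tree(SimulationConfig(num_tips=10, seed=25))
        at, _ = sc.simulate_history(t, RateModel(0.5, 0.5), seed=26)
        trees = sc.make_tree_set(at, n=4, jitter_sd=0.1, seed=27)
        post = sample_posterior(
            trees, gens_per_tree=100, burn_in=0, seed=28, tree_mode="cycle", thin=1
        )
        # deterministic schedule: blocks of gens_per_tree on each tree in turn
        assert post.draws["tree"].to_numpy()[0] == 0
        assert set(post.draws["tree"].unique()) == {0, 1, 2, 3}


class TestSteppingStone:
    def test_unit_likelihood_gives_zero_logz(self, small_trees, monkeypatch):
        """With likelihood identically 1 the marginal likelihood is 1."""
        monkeypatch.setattr(TreeLikelihood, "loglik", lambda self, models: 0.0)
        res = stepping_stone(
            small_trees, cfg=SteppingStoneConfig(n_stones=5, chain_length=100), seed=1
        )
        assert res.log_z == pytest.approx(0.0, abs=1e-12)
        assert res.se == pytest.approx(0.0, abs=1e-12)

    def test_beta_ladder_spans_unit_interval(self):
        betas = SteppingStoneConfig(n_stones=50, alpha=0.4).betas()
        assert betas[0] == 0.0 and betas[-1] == 1.0
        assert np.all(np.diff(betas) > 0)

    def test_matches_quadrature_oracle(self, small_trees):
        """Fixed hyperparameter, equal rates: logZ = log int L(q) Exp(q|1) dq."""
        engine = TreeLikelihood(small_trees[0])
        integral, _ = quad(
            lambda q: math.exp(engine.loglik(RateModel(q, q))) * math.exp(-q),
            0.0, 50.0,
        )
        res = stepping_stone(
            small_trees,
            ModelSpace(rates="equal"),
            PriorSpec(fixed_mean=1.0),
            SteppingStoneConfig(n_stones=30, chain_length=2000),
            seed=3,
        )
        assert abs(res.log_z - math.log(integral)) <= 3 * max(res.se, 1e-3)

    def test_stone_count_self_consistency(self, small_trees):
        common = dict(trees=small_trees, model_space=ModelSpace(rates="equal"),
                      prior=PriorSpec(fixed_mean=1.0))
        a = stepping_stone(
            cfg=SteppingStoneConfig(n_stones=10, chain_length=1500), seed=5, **common
        )
        b = stepping_stone(
            cfg=SteppingStoneConfig(n_stones=30, chain_length=1500), seed=6, **common
        )
        assert abs(a.log_z - b.log_z) <= 3 * math.sqrt(a.se**2 + b.se**2) + 0.02


class TestSubsampleTreeSet:
    def test_members_share_tip_sets(self):
        t = sc.simulate_tree(SimulationConfig(num_tips=30, seed=31))
        at, _ = sc.simulate_history(t, RateModel(0.5, 0.5), seed=32)
        trees = sc.make_tree_set(at, n=4, jitter_sd=0.1, seed=33)
        sub = subsample_tree_set(trees, "marine", 0.4, seed=34)
        assert len(sub) == 4
        tip_sets = {frozenset(m.labels) for m in sub}
        assert len(tip_sets) == 1
        assert len(sub.labels) < len(trees.labels)


class TestRunCladeAnalysis:
    def test_skip_reasons(self, tmp_path):
        small = sc.simulate_tree(SimulationConfig(num_tips=30, seed=41))
        at_small, _ = sc.simulate_history(small, RateModel(0.5, 0.5), seed=42)
        mono = sc.simulate_tree(SimulationConfig(num_tips=60, seed=43))
        at_mono, _ = sc.simulate_history(
            mono, RateModel(0, 0), root_state=sc.Habitat.MARINE, seed=44
        )
        report = sc.run_clade_analysis(
            {
                "clades": [
                    {"name": "too_small", "trees": sc.TreeSet([at_small])},
                    {"name": "one_habitat", "trees": sc.TreeSet([at_mono])},
                ],
                "mcmc": {"gens_per_tree": 50, "seed": 1},
                "model_test": {"enabled": False},
            }
        )
        assert report["clades"]["too_small"]["reason"] == "fewer than 50 tips"
        assert report["clades"]["one_habitat"]["reason"] == "single habitat"

    def test_eligible_clade_reports_summaries(self):
        tree = sc.simulate_tree(SimulationConfig(num_tips=60, seed=45))
        at, _ = sc.simulate_history(tree, RateModel(0.4, 0.4), seed=46)
        report = sc.run_clade_analysis(
            {
                "clades": [{"name": "ok", "trees": sc.TreeSet([at])}],
                "mcmc": {"gens_per_tree": 300, "seed": 2},
                "model_test": {"enabled": False},
                "subsample": {
                    "fractions": [0.2], "habitats": ["marine"],
                    "replicates": 1, "gens_per_tree": 100,
                },
            }
        )
        entry = report["clades"]["ok"]
        assert entry["eligible"]
        assert entry["posterior"]["q_mn_mean"] > 0
        assert entry["sensitivity"][0]["fraction"] == 0.2
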