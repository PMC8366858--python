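"""Sampler behaviour: determinism, conjugacy, selection, posterior summaries."""

import numpy as np
import pytest
from scipy import stats

from scoterhab.model import (
    MCMCConfig,
    PosteriorDraws,
    PriorSpec,
    inclusion_probabilities,
    prob_positive,
    sample_posterior,
    sample_posterior_variant,
)

CFG_FAST = dict(n_chains=1, n_adapt=200, n_burn=200, n_iter=400)


def make_draws(beta0, delta, gamma, sigma=None, r=None, names=None):
    """Hand-built PosteriorDraws (1 chain) for summary-function tests."""
    delta = np.asarray(delta, dtype=float)[None, ...]
    gamma = np.asarray(gamma, dtype=int)[None, ...]
    n = delta.shape[1]
    names = names or [f"t{i}" for i in range(delta.shape[2])]
    return PosteriorDraws(
        beta0=np.asarray(beta0, dtype=float)[None, :],
        delta=delta,
        gamma=gamma,
        gamma_adj=gamma,
        sigma=np.ones((1, n)) if sigma is None else np.asarray(sigma)[None, :],
        r=np.full((1, n), 1.0) if r is None else np.asarray(r)[None, :],
        w=None,
        term_names=names,
        family="nb",
        config=MCMCConfig(seed=0),
        priors=PriorSpec(),
    )


class TestSummaries:
    def test_inclusion_always_one_and_alternating(self):
        g = np.ones((1000, 2), dtype=int)
        g[::2, 1] = 0
        d = make_draws(np.zeros(1000), np.ones((1000, 2)), g)
        incl = inclusion_probabilities(d)
        assert incl["t0"] == 1.0
        assert incl["t1"] == pytest.approx(0.5)

    def test_prob_positive_spike_convention(self):
        # half the draws exclude the term (beta = 0 exactly): those count as
        # NOT positive; slab-conditional view ignores them
        g = np.ones((100, 1), dtype=int)
        g[50:, 0] = 0
        d = make_draws(np.zeros(100), np.full((100, 1), 2.0), g)
        assert prob_positive(d, "t0") == pytest.approx(0.5)
        assert prob_positive(d, "t0", slab_only=True) == 1.0


class TestSamplerContracts:
    def test_same_seed_bit_identical(self, small_design):
        y, X = small_design
        a = sample_posterior(y, X, config=MCMCConfig(seed=7, **CFG_FAST))
        b = sample_posterior(y, X, config=MCMCConfig(seed=7, **CFG_FAST))
        for f in ("beta0", "delta", "gamma", "sigma", "r"):
            np.testing.assert_array_equal(a.flat(f), b.flat(f))

    def test_different_seeds_differ(self, small_design):
        y, X = small_design
        a = sample_posterior(y, X, config=MCMCConfig(seed=7, **CFG_FAST))
        b = sample_posterior(y, X, config=MCMCConfig(seed=8, **CFG_FAST))
        assert not np.array_equal(a.flat("beta0"), b.flat("beta0"))

    def test_heredity_consistency_of_stored_draws(self, small_design):
        from scoterhab.model import default_terms, heredity_adjust

        y, X = small_design
        d = sample_posterior(y, X, config=MCMCConfig(seed=3, **CFG_FAST))
        g = d.flat("gamma")
        adj = heredity_adjust(g, default_terms())
        np.testing.assert_array_equal(adj, d.flat("gamma_adj"))
        np.testing.assert_array_equal(d.flat_beta(), d.flat("gamma_adj") * d.flat("delta"))

    def test_variant_dispatch_carries_family_parameters(self, small_design):
        y, X = small_design
        cfg = MCMCConfig(n_chains=1, n_adapt=50, n_burn=50, n_iter=100, seed=1)
        zip_d = sample_posterior_variant("zip", y[:100], X[:100], config=cfg)
        assert zip_d.family == "zip" and zip_d.w is not None and zip_d.r is None
        zinb_d = sample_posterior_variant("zinb", y[:100], X[:100], config=cfg)
        assert zinb_d.family == "zinb" and zinb_d.w is not None and zinb_d.r is not None
        assert np.all((zinb_d.flat("r") > 0) & (zinb_d.flat("r") < 10))
        assert np.all((zip_d.flat("w") > 0) & (zip_d.flat("w") < 1))

    def test_invalid_inputs_rejected(self, small_design):
        y, X = small_design
        with pytest.raises(ValueError):
            sample_posterior(y, X, family="weibull")
        with pytest.raises(ValueError):
            sample_posterior(y - 1, X)  # negative counts
        bad = X.copy()
        bad[0, 2] = np.nan
        with pytest.raises(ValueError):
            sample_posterior(y, bad)

    def test_run_metadata_recorded(self, small_design):
        y, X = small_design
        d = sample_posterior(
            y, X, config=MCMCConfig(n_chains=2, n_adapt=200, n_burn=200,
                                    n_iter=400, seed=3)
        )
        assert d.metadata["seed"] == 3
        assert d.metadata["prior_convention"] == "bugs-precision"
        assert "converged" in d.metadata and "rhat" in d.metadata

    def test_draws_roundtrip_to_files(self, small_design, tmp_path):
        import json
        import pandas as pd

        y, X = small_design
        d = sample_posterior(y, X, config=MCMCConfig(seed=3, **CFG_FAST))
        d.save(tmp_path / "draws.csv", tmp_path / "meta.json")
        df = pd.read_csv(tmp_path / "draws.csv")
        assert {"chain", "iter", "beta0", "sigma", "r", "beta.slope"} <= set(df.columns)
        assert len(df) == d.n_draws
        meta = json.loads((tmp_path / "meta.json").read_text())
        assert meta["family"] == "nb" and meta["config"]["seed"] == 3


class TestConjugacyAndSelection:
    def test_sigma_marginal_is_prior_when_all_gated(self, small_design):
        # with every indicator frozen at 0 the likelihood never touches
        # (delta, sigma), so the Gibbs subchain must reproduce the joint
        # prior: sigma ~ InvGamma(1, 1)
        y, X = small_design
        d = sample_posterior(
            y, X,
            config=MCMCConfig(n_chains=2, n_adapt=200, n_burn=300, n_iter=6000, seed=9),
            gamma_fix=np.zeros(13, dtype=int),
        )
        # thin to near-independence: the subchain's lag-1 autocorr is ~0.9
        sig = d.flat("sigma")[::40]
        ks = stats.kstest(sig, stats.invgamma(a=1.0, scale=1.0).cdf)
        assert ks.statistic < 0.08

    def test_strong_negative_effect_detected(self, paper_pipeline):
        # slope truth is -0.8 in the generating scenario
        d = paper_pipeline.design
        y, X = d.y[:1500], d.X[:1500]
        draws = sample_posterior(
            y, X, config=MCMCConfig(n_chains=1, n_adapt=300, n_burn=300,
                                    n_iter=800, seed=11)
        )
        assert prob_positive(draws, "slope") < 0.05
        assert inclusion_probabilities(draws)["slope"] > 0.9

    def test_gated_terms_follow_prior_under_null(self):
        # no-information limit: an indicator whose parents are absent cannot
        # change the likelihood, so its inclusion sits at the 0.5 prior;
        # informative null data shrink LINEAR terms well below 0.5 (Occam)
        rng = np.random.default_rng(0)
        n = 400
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 13))])
        y = rng.negative_binomial(0.5, 0.5 / (0.5 + 2.3), n)
        d = sample_posterior(
            y, X, config=MCMCConfig(n_chains=1, n_adapt=300, n_burn=300,
                                    n_iter=1500, seed=13)
        )
        incl_raw = inclusion_probabilities(d, adjusted=False)
        # interactions: parents jointly on ~25% of the time only
        for term in ("nao_x_bathy", "nao_x_dist", "bathy2", "dist2"):
            assert 0.3 < incl_raw[term] < 0.7
        for term in ("bathy", "slope", "wave", "latitude"):
            assert incl_raw[term] < 0.6
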