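"""Fit the NB regression with spike-and-slab variable selection.

Each coefficient is beta_k = gamma_adj_k * delta_k: a Bernoulli(0.5)
inclusion indicator (heredity-adjusted for quadratics and interactions)
times a Normal(0, sigma) slab effect. The Metropolis-within-Gibbs sampler
returns per-term posterior inclusion probabilities and P[beta > 0].
"""

import numpy as np

from scoterhab import (
    MCMCConfig,
    inclusion_probabilities,
    preset_scenarios,
    prob_positive,
    run_pipeline,
    sample_posterior,
)

scenario = preset_scenarios(seed=42)["paper_like"]
result = run_pipeline(scenario)
y, X = result.design.y, result.design.X

draws = sample_posterior(
    y, X, config=MCMCConfig(n_chains=3, n_adapt=400, n_burn=400,
                            n_iter=1200, seed=43)
)

incl = inclusion_probabilities(draws)
beta_mean = dict(zip(draws.term_names, draws.flat_beta().mean(axis=0)))
truth = dict(zip(draws.term_names, scenario.true_beta()))

print(f"n = {len(y)} cell-years; converged: {draws.metadata['converged']} "
      f"(max R-hat {max(draws.metadata['rhat'].values()):.3f})")
print(f"{'term':>12} {'incl':>6} {'P[b>0]':>7} {'post mean':>10} {'truth':>6}")
for t in draws.term_names:
    print(f"{t:>12} {incl[t]:>6.2f} {prob_positive(draws, t):>7.3f} "
          f"{beta_mean[t]:>10.3f} {truth[t]:>6.2f}")
r = draws.flat("r")
lo, hi = np.percentile(r, [2.5, 97.5])
print(f"\noverdispersion r: posterior mean {r.mean():.3f} "
      f"[{lo:.3f}, {hi:.3f}] (truth {scenario.r})")
print("-> the three generating effects are selected with probability ~1 and"
      "\n   recovered within a few hundredths; null terms are excluded.")
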