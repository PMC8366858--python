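"""Posterior-predictive model checking and convergence diagnostics.

Goodness of fit is assessed with the Freeman-Tukey discrepancy
T(y, mu) = sum_i (sqrt(y_i) - sqrt(mu_i))^2, a variance-stabilized measure
for counts. For each retained posterior draw the discrepancy of the observed
data and of a replicate simulated from the fitted family are compared; the
Bayesian p-value is the fraction of draws with T_rep >= T_obs (ties count,
the conservative convention). Values near 0 or 1 flag misfit; the lack-of-fit
flag here is two-sided at 0.1/0.9.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import PosteriorDraws, FAMILIES


@dataclass
class PPCResult:
    t_obs: np.ndarray
    t_rep: np.ndarray
    p_value: float
    seed: int
    family: str

    @property
    def lack_of_fit(self) -> bool:
        return self.p_value < 0.1 or self.p_value > 0.9


def freeman_tukey(y, mu) -> float:
    """T = sum_i (sqrt(y_i) - sqrt(mu_i))^2; zero iff y == mu elementwise."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if y.shape != mu.shape:
        raise ValueError("y and mu must have the same length")
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    return float(((np.sqrt(y) - np.sqrt(mu)) ** 2).sum())


def posterior_predictive_pvalue(
    draws: PosteriorDraws,
    y,
    X,
    family: str | None = None,
    seed: int = 0,
    max_draws: int | None = None,
) -> PPCResult:
    """Freeman-Tukey Bayesian p-value from retained draws.

    For each draw: mu = exp(beta0 + X beta); simulate y_rep from the fitted
    family at that draw; p = mean(T_rep >= T_obs). Seeded independently of
    the fit. ``max_draws`` evenly subsamples draws for speed.
    """
    family = family or draws.family
    if family != draws.family:
        raise ValueError(
            f"draws were fitted as {draws.family!r}, requested {family!r}"
        )
    y = np.asarray(y)
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    b0 = draws.flat("beta0")
    beta = draws.flat_beta()
    r = draws.flat("r") if draws.r is not None else None
    w = draws.flat("w") if draws.w is not None else None
    n = len(b0)
    idx = np.arange(n)
    if max_draws is not None and n > max_draws:
        idx = np.linspace(0, n - 1, max_draws).astype(int)
    fam = FAMILIES[family](y)
    t_obs = np.empty(len(idx))
    t_rep = np.empty(len(idx))
    Xp = X[:, 1:]
    for j, i in enumerate(idx):
        eta = b0[i] + Xp @ beta[i]
        mu = np.exp(eta)
        ri = r[i] if r is not None else None
        wi = w[i] if w is not None else None
        y_rep = fam.simulate(rng, eta, r=ri, w=wi)
        t_obs[j] = freeman_tukey(y, mu)
        t_rep[j] = freeman_tukey(y_rep, mu)
    p = float((t_rep >= t_obs).mean())
    return PPCResult(t_obs=t_obs, t_rep=t_rep, p_value=p, seed=seed, family=family)


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain Gelman-Rubin potential scale reduction factor.

    ``chains``: array (n_chains, n_draws). Each chain is split in half, the
    classic between/within variance ratio is computed over the split halves.
    """
    a = np.asarray(chains, dtype=float)
    if a.ndim != 2 or a.shape[0] < 2:
        raise ValueError("need >=2 chains of draws; run more chains")
    n = a.shape[1] // 2
    if n < 5:
        raise ValueError("need >=10 retained draws per chain")
    halves = np.concatenate([a[:, :n], a[:, n : 2 * n]], axis=0)
    m = halves.shape[0]
    means = halves.mean(axis=1)
    W = halves.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def gelman_rubin(draws: PosteriorDraws, parameter: str) -> float:
    """R-hat for a named parameter ("beta0", "sigma", "r", "beta.<term>")."""
    if parameter.startswith(("beta.", "delta.", "gamma.")):
        kind, term = parameter.split(".", 1)
        j = draws.term_names.index(term)
        arr = {"beta": draws.beta, "delta": draws.delta, "gamma": draws.gamma}[kind]
        return split_rhat(arr[:, :, j])
    arr = getattr(draws, parameter)
    if arr is None:
        raise ValueError(f"parameter {parameter!r} not present in these draws")
    return split_rhat(arr)
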