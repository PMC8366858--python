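"""Bayesian negative-binomial regression with indicator variable selection.

The count response y_i,t (scoters per grid cell per year) is modelled as

    y ~ NegBinom(p, r),  p = r / (r + mu),  log mu = beta0 + X @ beta

with r the overdispersion (size) parameter, so Var[y] = mu + mu^2/r: small r
means extreme clumping (almost all zeros, rare huge flocks). Each of the 13
predictor coefficients is a spike-and-slab product beta_k = gamma_adj_k *
delta_k where gamma_k ~ Bernoulli(0.5) is an inclusion indicator and
delta_k ~ Normal(0, sigma) the slab effect (Kuo-Mallick parameterization:
an excluded delta is refreshed from its prior). Strong heredity is enforced
by multiplying indicators: a quadratic or interaction only acts when every
parent linear term is also in (gamma_adj_k = gamma_k * prod of parent
gammas). Remaining priors: beta0 ~ Normal(0, 0.01) (precision convention by
default, i.e. sd 10), sigma ~ InvGamma(1, 1), r ~ Uniform(0, 10).

Fitting is Metropolis-within-Gibbs: random-walk MH on beta0, each active
delta_k and log r; exact Bernoulli full conditionals for each gamma_k;
conjugate inverse-gamma for sigma. Zero-inflated Poisson ("zip") and
zero-inflated NB ("zinb") variants add an intercept-only inflation weight
w ~ Uniform(0, 1) for the model-comparison step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .covariates import DESIGN_COLUMNS

TERM_NAMES = DESIGN_COLUMNS[1:]  # 13 predictor terms, fixed order

#: heredity DAG: higher-order term -> parent linear terms
TERM_PARENTS = {
    "bathy2": ["bathy"],
    "dist2": ["dist"],
    "wind2": ["wind"],
    "wave2": ["wave"],
    "nao_x_bathy": ["nao", "bathy"],
    "nao_x_dist": ["nao", "dist"],
}


@dataclass(frozen=True)
class ModelTerm:
    name: str
    index: int  # column index within the 13 predictor columns
    order: str  # "linear" | "quadratic" | "interaction"
    parents: tuple = ()


def default_terms(names=TERM_NAMES, parents_map=TERM_PARENTS) -> list[ModelTerm]:
    """Build and validate the term list with its heredity DAG."""
    idx = {n: i for i, n in enumerate(names)}
    terms = []
    for n in names:
        pars = tuple(parents_map.get(n, ()))
        for p in pars:
            if p not in idx:
                raise ValueError(f"term {n!r}: unknown parent {p!r}")
            if p in parents_map:
                raise ValueError(f"term {n!r}: parent {p!r} is not a linear term")
        if n in parents_map:
            order = "interaction" if len(pars) == 2 else "quadratic"
            if not (1 <= len(pars) <= 2):
                raise ValueError(f"term {n!r}: needs 1 or 2 parents")
        else:
            order = "linear"
        terms.append(ModelTerm(name=n, index=idx[n], order=order, parents=pars))
    return terms


def heredity_adjust(gamma: np.ndarray, terms: list[ModelTerm]) -> np.ndarray:
    """gamma_adj_k = gamma_k * prod over parents j of gamma_j."""
    gamma = np.asarray(gamma)
    adj = gamma.copy()
    name_idx = {t.name: t.index for t in terms}
    for t in terms:
        for p in t.parents:
            adj[..., t.index] = adj[..., t.index] * gamma[..., name_idx[p]]
    return adj


@dataclass(frozen=True)
class PriorSpec:
    """Priors; ``convention`` resolves the Normal second-argument ambiguity.

    "bugs-precision" (default): beta0 ~ N(0, precision 0.01) => sd 10, and
    sigma is the slab VARIANCE with sigma ~ InvGamma(1,1) (conjugate).
    "moment": beta0 ~ N(0, variance 0.01) => sd 0.1; sigma still the slab
    variance. Every fit records which convention was used.
    """

    convention: str = "bugs-precision"
    beta0_param: float = 0.01
    indicator_prior: float = 0.5
    sigma_shape: float = 1.0
    sigma_rate: float = 1.0
    r_lower: float = 0.0
    r_upper: float = 10.0

    def __post_init__(self):
        if not (0 < self.indicator_prior < 1):
            raise ValueError("indicator_prior must be in (0,1)")
        if not (0 <= self.r_lower < self.r_upper):
            raise ValueError("r bounds must be ordered and non-negative")
        if self.sigma_shape <= 0 or self.sigma_rate <= 0:
            raise ValueError("InvGamma hyperparameters must be positive")
        if self.convention not in ("bugs-precision", "moment"):
            raise ValueError(f"unknown prior convention {self.convention!r}")

    @property
    def beta0_sd(self) -> float:
        if self.convention == "bugs-precision":
            return 1.0 / np.sqrt(self.beta0_param)
        return np.sqrt(self.beta0_param)


@dataclass
class MCMCConfig:
    n_chains: int = 3
    n_adapt: int = 500
    n_burn: int = 500
    n_iter: int = 2000
    thin: int = 1
    seed: int = 0
    target_accept: float = 0.44  # 1-D RW optimum, inside the 20-50% band

    def __post_init__(self):
        for f in ("n_chains", "n_adapt", "n_burn", "n_iter", "thin"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be positive")


# ---------------------------------------------------------------------------
# likelihoods


def nb_logpmf(y, mu, r):
    """Log pmf of NegBinom with mean mu and size r; p = r/(r+mu)."""
    y = np.asarray(y)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0) or np.any(np.asarray(r) <= 0):
        raise ValueError("mu and r must be positive")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must be non-negative integers")
    lr = np.log(r)
    lrm = np.log(r + mu)
    return (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1)
        + r * (lr - lrm)
        + y * (np.log(mu) - lrm)
    )


def nb_pmf(y, mu, r):
    return np.exp(nb_logpmf(y, mu, r))


class _NBFamily:
    """NB log-likelihood split into an r-only part (cached) and a mu part."""

    name = "nb"
    has_r = True
    has_w = False

    def __init__(self, y):
        self.y = np.asarray(y, dtype=float)
        self.n = len(self.y)
        self._const = -gammaln(self.y + 1).sum()
        self._r_cache = (None, None)

    def _A(self, r):
        rc, val = self._r_cache
        if rc != r:
            val = gammaln(self.y + r).sum() - self.n * gammaln(r) + self._const
            self._r_cache = (r, val)
        return val

    def loglik(self, eta, r=None, w=None):
        mu = np.exp(eta)
        lrm = np.log(r + mu)
        return (
            self._A(r)
            + self.n * r * np.log(r)
            - r * lrm.sum()
            + (self.y * (eta - lrm)).sum()
        )

    def simulate(self, rng, eta, r=None, w=None):
        mu = np.exp(eta)
        p = r / (r + mu)
        return rng.negative_binomial(r, p)


class _ZIPFamily:
    name = "zip"
    has_r = False
    has_w = True

    def __init__(self, y):
        self.y = np.asarray(y, dtype=float)
        self.zero = self.y == 0
        self._const = -gammaln(self.y[~self.zero] + 1).sum()

    def loglik(self, eta, r=None, w=None):
        mu = np.exp(eta)
        # zeros: log(w + (1-w) e^-mu); positives: log(1-w) + Poisson logpmf
        lz = np.logaddexp(np.log(w), np.log1p(-w) - mu[self.zero]).sum()
        yp = self.y[~self.zero]
        lp = (
            np.log1p(-w) * (~self.zero).sum()
            - mu[~self.zero].sum()
            + (yp * eta[~self.zero]).sum()
            + self._const
        )
        return lz + lp

    def simulate(self, rng, eta, r=None, w=None):
        y = rng.poisson(np.exp(eta))
        y[rng.random(len(y)) < w] = 0
        return y


class _ZINBFamily(_NBFamily):
    name = "zinb"
    has_r = True
    has_w = True

    def __init__(self, y):
        super().__init__(y)
        self.zero = self.y == 0

    def loglik(self, eta, r=None, w=None):
        mu = np.exp(eta)
        lrm = np.log(r + mu)
        lognb0 = r * (np.log(r) - lrm[self.zero])  # NB logpmf at y=0
        lz = np.logaddexp(np.log(w), np.log1p(-w) + lognb0).sum()
        pos = ~self.zero
        yp = self.y[pos]
        lpos = (
            np.log1p(-w) * pos.sum()
            + (gammaln(yp + r) - gammaln(r) - gammaln(yp + 1)).sum()
            + r * (np.log(r) - lrm[pos]).sum()
            + (yp * (eta[pos] - lrm[pos])).sum()
        )
        return lz + lpos

    def simulate(self, rng, eta, r=None, w=None):
        mu = np.exp(eta)
        y = rng.negative_binomial(r, r / (r + mu))
        y[rng.random(len(y)) < w] = 0
        return y


FAMILIES = {"nb": _NBFamily, "zip": _ZIPFamily, "zinb": _ZINBFamily}


def log_likelihood(y, X, beta0, beta, r, family: str = "nb", w: float = None):
    """Full-data log-likelihood at a given parameter point.

    X is the full 14-column design matrix (intercept first); beta the 13
    effects. Rejects non-finite linear predictors, naming the first bad row.
    """
    X = np.asarray(X, dtype=float)
    eta = beta0 + X[:, 1:] @ np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(eta)):
        bad = int(np.argmax(~np.isfinite(eta)))
        raise ValueError(f"non-finite linear predictor at row {bad}")
    fam = FAMILIES[family](np.asarray(y))
    return float(fam.loglik(eta, r=r, w=w))


# ---------------------------------------------------------------------------
# posterior container


@dataclass
class PosteriorDraws:
    """Retained MCMC draws, shape (n_chains, n_saved[, n_terms])."""

    beta0: np.ndarray
    delta: np.ndarray
    gamma: np.ndarray
    gamma_adj: np.ndarray
    sigma: np.ndarray
    r: np.ndarray | None
    w: np.ndarray | None
    term_names: list[str]
    family: str
    config: MCMCConfig
    priors: PriorSpec
    acceptance: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def beta(self) -> np.ndarray:
        return self.gamma_adj * self.delta

    @property
    def n_draws(self) -> int:
        return self.beta0.shape[0] * self.beta0.shape[1]

    def flat(self, name) -> np.ndarray:
        a = getattr(self, name)
        return a.reshape(-1, *a.shape[2:])

    def flat_beta(self) -> np.ndarray:
        return self.beta.reshape(-1, self.beta.shape[-1])

    def to_frame(self) -> pd.DataFrame:
        C, S = self.beta0.shape
        d = {
            "chain": np.repeat(np.arange(C), S),
            "iter": np.tile(np.arange(S), C),
            "beta0": self.flat("beta0"),
        }
        for j, t in enumerate(self.term_names):
            d[f"delta.{t}"] = self.flat("delta")[:, j]
            d[f"gamma.{t}"] = self.flat("gamma")[:, j]
            d[f"beta.{t}"] = self.flat_beta()[:, j]
        d["sigma"] = self.flat("sigma")
        if self.r is not None:
            d["r"] = self.flat("r")
        if self.w is not None:
            d["w"] = self.flat("w")
        return pd.DataFrame(d)

    def save(self, draws_csv, meta_json):
        self.to_frame().to_csv(draws_csv, index=False)
        meta = {
            "family": self.family,
            "config": asdict(self.config),
            "priors": asdict(self.priors),
            "acceptance": self.acceptance,
            **self.metadata,
        }
        with open(meta_json, "w") as fh:
            json.dump(meta, fh, indent=1, default=float)


def inclusion_probabilities(draws: PosteriorDraws, adjusted: bool = True) -> pd.Series:
    """Posterior inclusion probability per term: mean of gamma_adj (default,
    the heredity-respecting probability that the term ACTS in the model) or
    of raw gamma."""
    g = draws.flat("gamma_adj" if adjusted else "gamma")
    return pd.Series(g.mean(axis=0), index=draws.term_names)


def prob_positive(draws: PosteriorDraws, term: str, slab_only: bool = False) -> float:
    """P[beta_k > 0] over retained draws.

    Spike draws (beta exactly 0, term excluded) count as NOT positive by
    default; ``slab_only`` conditions on inclusion instead.
    """
    j = draws.term_names.index(term)
    b = draws.flat_beta()[:, j]
    if slab_only:
        inc = draws.flat("gamma_adj")[:, j] == 1
        if not inc.any():
            return float("nan")
        b = b[inc]
    return float((b > 0).mean())


# ---------------------------------------------------------------------------
# sampler


class _Adapt:
    """Robbins-Monro scale adaptation toward a target acceptance rate."""

    def __init__(self, scale, target):
        self.scale = scale
        self.target = target
        self.acc = 0
        self.tries = 0

    def update(self, accepted):
        self.acc += accepted
        self.tries += 1

    def adapt(self):
        if self.tries == 0:
            return
        rate = self.acc / self.tries
        self.scale *= np.exp(np.clip(rate - self.target, -0.5, 0.5))
        self.acc = 0
        self.tries = 0

    def rate(self):
        return self.acc / max(self.tries, 1)


def _run_chain(y, Xp, terms, priors, cfg, rng, family_name, gamma_fix, n_save):
    fam = FAMILIES[family_name](y)
    K = Xp.shape[1]
    parent_idx = [
        np.array([terms_i.index for terms_i in terms if terms_i.name in t.parents], int)
        for t in terms
    ]
    children = [
        np.array([c.index for c in terms if terms[k].name in c.parents], int)
        for k in range(K)
    ]

    def adj_of(gam):
        a = gam.copy()
        for k in range(K):
            if len(parent_idx[k]):
                a[k] = gam[k] * gam[parent_idx[k]].prod()
        return a

    # dispersed start
    beta0 = rng.normal(0, 1)
    delta = rng.normal(0, 1, K)
    if gamma_fix is None:
        gamma = rng.integers(0, 2, K)
    else:
        gamma = np.asarray(gamma_fix, dtype=int).copy()
    sigma = 1.0
    r = float(np.exp(rng.uniform(np.log(0.05), np.log(5.0)))) if fam.has_r else None
    w = float(rng.uniform(0.1, 0.9)) if fam.has_w else None

    adj = adj_of(gamma)
    eta = beta0 + Xp @ (adj * delta)
    cur_ll = fam.loglik(eta, r=r, w=w)

    sd0 = priors.beta0_sd
    a0, b0 = priors.sigma_shape, priors.sigma_rate
    logit_pi = np.log(priors.indicator_prior) - np.log1p(-priors.indicator_prior)

    ad_b0 = _Adapt(0.1, cfg.target_accept)
    ad_d = [_Adapt(0.2, cfg.target_accept) for _ in range(K)]
    ad_r = _Adapt(0.3, cfg.target_accept)
    ad_w = _Adapt(0.5, cfg.target_accept)

    total = cfg.n_adapt + cfg.n_burn + cfg.n_iter
    out = {
        "beta0": np.empty(n_save),
        "delta": np.empty((n_save, K)),
        "gamma": np.empty((n_save, K), dtype=int),
        "gamma_adj": np.empty((n_save, K), dtype=int),
        "sigma": np.empty(n_save),
        "r": np.empty(n_save) if fam.has_r else None,
        "w": np.empty(n_save) if fam.has_w else None,
    }
    save_i = 0
    final_rates = {}

    for it in range(total):
        adapting = it < cfg.n_adapt

        # --- beta0: RW-MH, prior N(0, sd0^2)
        prop = beta0 + rng.normal(0, ad_b0.scale)
        eta_p = eta + (prop - beta0)
        ll_p = fam.loglik(eta_p, r=r, w=w)
        lacc = ll_p - cur_ll + (beta0**2 - prop**2) / (2 * sd0**2)
        acc = np.log(rng.random()) < lacc
        if acc:
            beta0, eta, cur_ll = prop, eta_p, ll_p
        if adapting:
            ad_b0.update(acc)

        # --- delta_k
        for k in range(K):
            if adj[k] == 0:
                # Kuo-Mallick: excluded slab refreshed from its prior
                delta[k] = rng.normal(0, np.sqrt(sigma))
                continue
            prop = delta[k] + rng.normal(0, ad_d[k].scale)
            eta_p = eta + Xp[:, k] * (prop - delta[k])
            ll_p = fam.loglik(eta_p, r=r, w=w)
            lacc = ll_p - cur_ll + (delta[k] ** 2 - prop**2) / (2 * sigma)
            acc = np.log(rng.random()) < lacc
            if acc:
                delta[k], eta, cur_ll = prop, eta_p, ll_p
            if adapting:
                ad_d[k].update(acc)

        # --- gamma_k: exact two-point full conditional (heredity-aware).
        # Flipping gamma_k changes gamma_adj only at k and its children, so
        # the flipped predictor is an incremental update of the cached eta.
        if gamma_fix is None:
            for k in range(K):
                g_flip = gamma.copy()
                g_flip[k] = 1 - gamma[k]
                a_flip = adj_of(g_flip)
                if np.array_equal(a_flip, adj):
                    # gated out by an absent parent: likelihood is flat in
                    # gamma_k, so the full conditional is the prior
                    gamma[k] = int(rng.random() < priors.indicator_prior)
                    continue
                diff = np.nonzero(a_flip != adj)[0]
                eta_flip = eta + Xp[:, diff] @ ((a_flip - adj) * delta)[diff]
                ll_flip = fam.loglik(eta_flip, r=r, w=w)
                if gamma[k] == 1:
                    ll1, ll0 = cur_ll, ll_flip
                else:
                    ll1, ll0 = ll_flip, cur_ll
                p1 = 1.0 / (1.0 + np.exp(-np.clip(logit_pi + ll1 - ll0, -700, 700)))
                new_val = int(rng.random() < p1)
                if new_val != gamma[k]:
                    gamma[k] = new_val
                    adj, eta, cur_ll = a_flip, eta_flip, ll_flip

        # --- sigma: conjugate InvGamma(a0 + K/2, b0 + sum delta^2 / 2)
        a_post = a0 + K / 2.0
        b_post = b0 + (delta**2).sum() / 2.0
        sigma = b_post / rng.gamma(a_post)

        # --- r: RW-MH on log r, Uniform(0, r_upper) prior
        if fam.has_r:
            prop = float(np.exp(np.log(r) + rng.normal(0, ad_r.scale)))
            if priors.r_lower < prop < priors.r_upper:
                ll_p = fam.loglik(eta, r=prop, w=w)
                lacc = ll_p - cur_ll + np.log(prop) - np.log(r)  # Jacobian
                acc = np.log(rng.random()) < lacc
                if acc:
                    r, cur_ll = prop, ll_p
            else:
                acc = False
            if adapting:
                ad_r.update(acc)

        # --- w: RW-MH on logit w, Uniform(0,1) prior
        if fam.has_w:
            lw = np.log(w) - np.log1p(-w) + rng.normal(0, ad_w.scale)
            prop = 1.0 / (1.0 + np.exp(-lw))
            ll_p = fam.loglik(eta, r=r, w=prop)
            jac = (np.log(prop) + np.log1p(-prop)) - (np.log(w) + np.log1p(-w))
            acc = np.log(rng.random()) < ll_p - cur_ll + jac
            if acc:
                w, cur_ll = prop, ll_p
            if adapting:
                ad_w.update(acc)

        if adapting and (it + 1) % 50 == 0:
            ad_b0.adapt()
            for a in ad_d:
                a.adapt()
            ad_r.adapt()
            ad_w.adapt()

        keep = it >= cfg.n_adapt + cfg.n_burn
        if keep and (it - cfg.n_adapt - cfg.n_burn) % cfg.thin == 0:
            out["beta0"][save_i] = beta0
            out["delta"][save_i] = delta
            out["gamma"][save_i] = gamma
            out["gamma_adj"][save_i] = adj
            out["sigma"][save_i] = sigma
            if fam.has_r:
                out["r"][save_i] = r
            if fam.has_w:
                out["w"][save_i] = w
            save_i += 1

    final_rates = {
        "beta0": ad_b0.scale,
        "r": ad_r.scale if fam.has_r else None,
    }
    return out, final_rates


def sample_posterior(
    y,
    X,
    terms: list[ModelTerm] | None = None,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    family: str = "nb",
    gamma_fix=None,
    rhat_threshold: float = 1.1,
) -> PosteriorDraws:
    """Fit the spike-and-slab count regression by Metropolis-within-Gibbs.

    Parameters
    ----------
    y, X:
        Counts and the 14-column design matrix (intercept first).
    family:
        "nb" (default), "zip", or "zinb".
    gamma_fix:
        Optional length-13 0/1 vector freezing the inclusion indicators
        (e.g. all zeros for prior/conjugacy checks).
    rhat_threshold:
        Convergence is assessed with split-chain Gelman-Rubin on beta0,
        sigma, r and every beta with adjusted inclusion > 0.2; failures are
        flagged in ``metadata`` (never silently ignored).
    """
    from .checking import split_rhat  # local import to avoid cycle

    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    y = np.asarray(y)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must be non-negative integers")
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix must be finite")
    terms = terms if terms is not None else default_terms()
    priors = priors or PriorSpec()
    config = config or MCMCConfig()
    Xp = X[:, 1:]
    if Xp.shape[1] != len(terms):
        raise ValueError("design matrix predictor columns must match terms")

    n_save = (config.n_iter + config.thin - 1) // config.thin
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains = []
    rates = []
    for c in range(config.n_chains):
        rng = np.random.Generator(np.random.PCG64(seeds[c]))
        out, rr = _run_chain(
            y, Xp, terms, priors, config, rng, family, gamma_fix, n_save
        )
        chains.append(out)
        rates.append(rr)

    def stack(name):
        if chains[0][name] is None:
            return None
        return np.stack([c[name] for c in chains])

    draws = PosteriorDraws(
        beta0=stack("beta0"),
        delta=stack("delta"),
        gamma=stack("gamma"),
        gamma_adj=stack("gamma_adj"),
        sigma=stack("sigma"),
        r=stack("r"),
        w=stack("w"),
        term_names=[t.name for t in terms],
        family=family,
        config=config,
        priors=priors,
        acceptance={"proposal_scales": rates},
    )

    rhats = {}
    if config.n_chains >= 2:
        rhats["beta0"] = split_rhat(draws.beta0)
        rhats["sigma"] = split_rhat(draws.sigma)
        if draws.r is not None:
            rhats["r"] = split_rhat(draws.r)
        incl = inclusion_probabilities(draws)
        for j, t in enumerate(draws.term_names):
            if incl[t] > 0.2:
                rhats[f"beta.{t}"] = split_rhat(draws.beta[:, :, j])
        draws.metadata["converged"] = all(v < rhat_threshold for v in rhats.values())
    draws.metadata["rhat"] = rhats
    draws.metadata["seed"] = config.seed
    draws.metadata["prior_convention"] = priors.convention
    return draws


def sample_posterior_variant(family, y, X, **kwargs) -> PosteriorDraws:
    """Fit one of the compared observation families: "nb", "zip" or "zinb"."""
    return sample_posterior(y, X, family=family, **kwargs)
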