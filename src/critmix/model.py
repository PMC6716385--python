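"""Latent criterion-group mixture model for binary categorization decisions.

Each respondent entry p belongs to a latent group z_p drawn from mixing
probabilities pi.  Within group g, item i has a scale value beta_{g,i}
(how strongly the item displays the group's categorization criterion) and the
entry has a threshold theta_p ~ Normal(mu_g, 1) (how much evidence the
respondent requires).  A *yes* answer to item i is Bernoulli with

    r_pi = 1 / (1 + exp(-alpha_g (beta_{g,i} - theta_p))),

an S-shaped curve through .50 at beta = theta whose steepness at that point of
subjective equality is set by the group-specific alpha_g > 0.  Distinct beta
profiles across groups capture criterial vagueness; the spread of theta within
a group captures degree vagueness.

Priors: pi ~ Dirichlet(1,...,1); beta_{g,i}, mu_g ~ Normal(0, 1);
alpha_g half-normal with unit variance; theta_p ~ Normal(mu_{z_p}, 1)
("precision 1" throughout, i.e. unit variance).

Posterior sampling is Metropolis-within-Gibbs: exact categorical Gibbs for z,
conjugate Dirichlet for pi, conjugate normal for mu, random-walk Metropolis
for beta and theta, log-scale random walk for alpha.  Proposal scales adapt
toward ~0.4 acceptance during burn-in only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .data import MergedMatrix

HALF_NORMAL_MEAN = float(np.sqrt(2.0 / np.pi))  # prior mean of alpha


@dataclass
class ModelParameters:
    """One complete parameter state (simulation truth or an MCMC state).

    Group indices are 0-based internally.
    """

    pi: np.ndarray      # (G,) mixing probabilities
    z: np.ndarray       # (P,) int group index per entry
    beta: np.ndarray    # (G, I) item scale values per group
    theta: np.ndarray   # (P,) thresholds
    mu: np.ndarray      # (G,) group threshold means
    alpha: np.ndarray   # (G,) response-curve steepness, > 0

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.z = np.asarray(self.z, dtype=int)
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.theta = np.asarray(self.theta, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        G = self.pi.shape[0]
        if G < 1:
            raise ValueError("need at least one group")
        if not np.isclose(self.pi.sum(), 1.0) or (self.pi < 0).any():
            raise ValueError("pi must be a probability simplex")
        if self.beta.shape[0] != G or self.mu.shape[0] != G or self.alpha.shape[0] != G:
            raise ValueError("beta, mu, alpha must have one row/element per group")
        if (self.alpha <= 0).any():
            raise ValueError("alpha must be strictly positive")
        if self.z.shape != self.theta.shape:
            raise ValueError("z and theta must have matching length")
        if len(self.z) and (self.z.min() < 0 or self.z.max() >= G):
            raise ValueError("z out of range")

    @property
    def n_groups(self) -> int:
        return self.pi.shape[0]

    @property
    def n_items(self) -> int:
        return self.beta.shape[1]

    @property
    def n_entries(self) -> int:
        return self.z.shape[0]

    def permute_groups(self, perm) -> "ModelParameters":
        """Relabel groups by ``perm`` (new label g holds old group perm[g])."""
        perm = np.asarray(perm, dtype=int)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        return ModelParameters(
            pi=self.pi[perm], z=inv[self.z], beta=self.beta[perm],
            theta=self.theta.copy(), mu=self.mu[perm], alpha=self.alpha[perm],
        )


def response_probability(beta_gi, theta_p, alpha_g):
    """Probability of a *yes* answer: logistic in alpha * (beta - theta).

    Equals .50 exactly at beta = theta (the point of subjective equality),
    rises toward 1 as beta - theta grows positive and falls toward 0 as it
    grows negative; alpha sets the steepness at the midpoint.
    """
    alpha_g = np.asarray(alpha_g, dtype=float)
    if np.any(alpha_g <= 0):
        raise ValueError("alpha must be strictly positive")
    eta = alpha_g * (np.asarray(beta_gi, dtype=float) - np.asarray(theta_p, dtype=float))
    return stats.logistic.cdf(eta)


def _bernoulli_loglik_matrix(x: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Elementwise log-likelihood; NaN cells (unknown answers) contribute 0."""
    # log p = -softplus(-eta), log(1-p) = -softplus(eta)
    out = np.where(np.nan_to_num(x) > 0.5,
                   -np.logaddexp(0.0, -eta),
                   -np.logaddexp(0.0, eta))
    return np.where(np.isnan(x), 0.0, out)


def complete_loglik(params: ModelParameters, m: MergedMatrix) -> float:
    """Log-likelihood of the observed cells given a full parameter state."""
    if params.n_entries != m.n_entries or params.n_items != m.n_items:
        raise ValueError("parameter dimensions do not match the matrix")
    if params.n_entries == 0 or params.n_items == 0:
        return 0.0
    eta = params.alpha[params.z][:, None] * (
        params.beta[params.z] - params.theta[:, None]
    )
    return float(_bernoulli_loglik_matrix(m.x, eta).sum())


def log_prior(params: ModelParameters) -> float:
    """Joint log prior density of a parameter state (see module docstring)."""
    G = params.n_groups
    lp = float(stats.dirichlet.logpdf(_simplex_interior(params.pi), np.ones(G)))
    lp += float(stats.norm.logpdf(params.beta).sum())
    lp += float(stats.norm.logpdf(params.mu).sum())
    lp += float(stats.halfnorm.logpdf(params.alpha).sum())
    lp += float(stats.norm.logpdf(params.theta, loc=params.mu[params.z]).sum())
    lp += float(np.log(params.pi[params.z]).sum())
    return lp


def _simplex_interior(pi: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Nudge boundary simplexes inside the support for density evaluation."""
    pi = np.clip(pi, eps, None)
    return pi / pi.sum()


# --------------------------------------------------------------------------
# sampler
# --------------------------------------------------------------------------

@dataclass
class PosteriorSamples:
    """Post-burn-in draws from all chains.

    Arrays are indexed (chain, draw, ...).  ``z`` uses 0-based group labels.
    """

    pi: np.ndarray      # (C, D, G)
    z: np.ndarray       # (C, D, P) int8/int16
    beta: np.ndarray    # (C, D, G, I)
    theta: np.ndarray   # (C, D, P)
    mu: np.ndarray      # (C, D, G)
    alpha: np.ndarray   # (C, D, G)
    n_chains: int
    n_iter: int
    n_burnin: int
    seed: int
    relabeled: bool = False

    @property
    def n_draws(self) -> int:
        return self.pi.shape[1]

    @property
    def n_groups(self) -> int:
        return self.pi.shape[2]

    @property
    def n_entries(self) -> int:
        return self.z.shape[2]

    @property
    def n_items(self) -> int:
        return self.beta.shape[3]

    def draw(self, chain: int, idx: int) -> ModelParameters:
        return ModelParameters(
            pi=self.pi[chain, idx], z=self.z[chain, idx].astype(int),
            beta=self.beta[chain, idx], theta=self.theta[chain, idx],
            mu=self.mu[chain, idx], alpha=self.alpha[chain, idx],
        )


def _z_log_weights(x, beta, theta, mu, alpha, log_pi):
    """(P, G) unnormalized log conditional of each entry's group label."""
    P = theta.shape[0]
    G = beta.shape[0]
    w = np.empty((P, G))
    for g in range(G):
        eta = alpha[g] * (beta[g][None, :] - theta[:, None])
        w[:, g] = (_bernoulli_loglik_matrix(x, eta).sum(axis=1)
                   + stats.norm.logpdf(theta, loc=mu[g])
                   + log_pi[g])
    return w


def _categorical_rows(rng, logw):
    """Draw one categorical index per row of a matrix of log weights."""
    logw = logw - logw.max(axis=1, keepdims=True)
    p = np.exp(logw)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(p.shape[0])
    return (p.cumsum(axis=1) < u[:, None]).sum(axis=1)


class _ChainState:
    """Mutable state of one MCMC chain, with adaptive proposal scales."""

    def __init__(self, x: np.ndarray, G: int, rng: np.random.Generator):
        P, I = x.shape
        self.x = x
        self.obs = ~np.isnan(x)
        self.G, self.P, self.I = G, P, I
        self.rng = rng
        # overdispersed start from the prior
        self.pi = rng.dirichlet(np.ones(G))
        self.z = rng.integers(0, G, P)
        self.beta = rng.normal(size=(G, I))
        self.mu = rng.normal(size=G)
        self.theta = rng.normal(self.mu[self.z], 1.0)
        self.alpha = np.abs(rng.normal(size=G)) + 0.1
        self.step_beta = np.full((G, I), 0.5)
        self.step_theta = np.full(P, 0.5)
        self.step_alpha = np.full(G, 0.3)

    # -- individual kernel updates ------------------------------------
    def update_z(self) -> None:
        logw = _z_log_weights(self.x, self.beta, self.theta, self.mu,
                              self.alpha, np.log(_simplex_interior(self.pi)))
        self.z = _categorical_rows(self.rng, logw)

    def update_pi(self) -> None:
        counts = np.bincount(self.z, minlength=self.G)
        self.pi = self.rng.dirichlet(1.0 + counts)

    def update_mu(self) -> None:
        # conjugate: theta_p ~ N(mu_g, 1), mu_g ~ N(0, 1)
        for g in range(self.G):
            th = self.theta[self.z == g]
            prec = 1.0 + th.size
            self.mu[g] = self.rng.normal(th.sum() / prec, np.sqrt(1.0 / prec))

    def _item_loglik_by_group(self, beta: np.ndarray) -> np.ndarray:
        """(G, I) log-lik sums over each group's entries, given beta rows."""
        out = np.zeros((self.G, self.I))
        for g in range(self.G):
            sel = self.z == g
            if not sel.any():
                continue
            eta = self.alpha[g] * (beta[g][None, :] - self.theta[sel][:, None])
            out[g] = _bernoulli_loglik_matrix(self.x[sel], eta).sum(axis=0)
        return out

    def update_beta(self, adapt: float | None) -> None:
        prop = self.beta + self.step_beta * self.rng.normal(size=self.beta.shape)
        cur = self._item_loglik_by_group(self.beta) - 0.5 * self.beta**2
        new = self._item_loglik_by_group(prop) - 0.5 * prop**2
        accept = np.log(self.rng.random(self.beta.shape)) < (new - cur)
        self.beta = np.where(accept, prop, self.beta)
        if adapt is not None:
            self.step_beta *= np.exp(adapt * (accept - 0.4))

    def update_theta(self, adapt: float | None) -> None:
        prop = self.theta + self.step_theta * self.rng.normal(size=self.P)
        a = self.alpha[self.z][:, None]
        b = self.beta[self.z]
        m = self.mu[self.z]
        cur = (_bernoulli_loglik_matrix(self.x, a * (b - self.theta[:, None])).sum(axis=1)
               - 0.5 * (self.theta - m) ** 2)
        new = (_bernoulli_loglik_matrix(self.x, a * (b - prop[:, None])).sum(axis=1)
               - 0.5 * (prop - m) ** 2)
        accept = np.log(self.rng.random(self.P)) < (new - cur)
        self.theta = np.where(accept, prop, self.theta)
        if adapt is not None:
            self.step_theta *= np.exp(adapt * (accept - 0.4))

    def update_alpha(self, adapt: float | None) -> None:
        for g in range(self.G):
            sel = self.z == g
            prop = self.alpha[g] * np.exp(self.step_alpha[g] * self.rng.normal())
            if sel.any():
                d = self.beta[g][None, :] - self.theta[sel][:, None]
                xg = self.x[sel]
                cur_ll = _bernoulli_loglik_matrix(xg, self.alpha[g] * d).sum()
                new_ll = _bernoulli_loglik_matrix(xg, prop * d).sum()
            else:
                cur_ll = new_ll = 0.0
            # half-normal prior + log-scale proposal Jacobian
            logr = (new_ll - cur_ll
                    - 0.5 * (prop**2 - self.alpha[g] ** 2)
                    + np.log(prop) - np.log(self.alpha[g]))
            accepted = np.log(self.rng.random()) < logr
            if accepted:
                self.alpha[g] = prop
            if adapt is not None:
                self.step_alpha[g] *= np.exp(adapt * (float(accepted) - 0.4))

    def translate_groups(self) -> None:
        """Exact group move along the location ridge of each group.

        The likelihood depends on beta_{g,i} - theta_p only, so a common shift
        of (beta_g, mu_g, theta_{z=g}) is a flat direction that random-walk
        updates cross very slowly.  Sampling the shift from its exact Gaussian
        conditional (driven by the beta and mu priors; the theta-given-mu and
        likelihood terms are invariant) restores mixing across that ridge.
        """
        for g in range(self.G):
            prec = self.I + 1.0
            delta = self.rng.normal(-(self.beta[g].sum() + self.mu[g]) / prec,
                                    np.sqrt(1.0 / prec))
            self.beta[g] += delta
            self.mu[g] += delta
            self.theta[self.z == g] += delta

    def sweep(self, adapt: float | None) -> None:
        self.update_z()
        self.update_pi()
        self.update_theta(adapt)
        self.update_mu()
        self.update_beta(adapt)
        self.update_alpha(adapt)
        self.translate_groups()


def fit_mcmc(
    m: MergedMatrix,
    G: int = 2,
    n_chains: int = 3,
    n_iter: int = 10_000,
    n_burnin: int = 4_000,
    seed: int = 0,
    progress: bool = False,
) -> PosteriorSamples:
    """Sample the mixture posterior by Metropolis-within-Gibbs.

    Runs ``n_chains`` independent chains of ``n_iter`` sweeps each and keeps
    the draws after ``n_burnin``.  Proposal-scale adaptation is confined to
    the burn-in so the retained draws come from a fixed kernel.  Chain c uses
    the deterministic seed ``seed + c``, so identical calls reproduce
    identical draws.
    """
    if G < 2:
        raise ValueError("G must be at least 2")
    if n_iter <= n_burnin:
        raise ValueError("n_iter must exceed n_burnin")
    if m.n_entries < 2 or m.n_items < 2:
        raise ValueError("need at least a 2 x 2 matrix")
    x = np.asarray(m.x, dtype=float)
    if np.isnan(x).all() and x.size == 0:
        raise ValueError("empty matrix")

    P, I = x.shape
    D = n_iter - n_burnin
    zdtype = np.int8 if G < 127 else np.int16
    out = PosteriorSamples(
        pi=np.empty((n_chains, D, G)), z=np.empty((n_chains, D, P), dtype=zdtype),
        beta=np.empty((n_chains, D, G, I)), theta=np.empty((n_chains, D, P)),
        mu=np.empty((n_chains, D, G)), alpha=np.empty((n_chains, D, G)),
        n_chains=n_chains, n_iter=n_iter, n_burnin=n_burnin, seed=seed,
    )
    for c in range(n_chains):
        rng = np.random.default_rng(seed + c)
        st = _ChainState(x, G, rng)
        for t in range(n_iter):
            adapt = min(0.5, 2.0 / np.sqrt(t + 1.0)) if t < n_burnin else None
            st.sweep(adapt)
            if t >= n_burnin:
                d = t - n_burnin
                out.pi[c, d] = st.pi
                out.z[c, d] = st.z
                out.beta[c, d] = st.beta
                out.theta[c, d] = st.theta
                out.mu[c, d] = st.mu
                out.alpha[c, d] = st.alpha
        if progress:
            print(f"chain {c + 1}/{n_chains} done")
    return out


# --------------------------------------------------------------------------
# label switching
# --------------------------------------------------------------------------

def _pearson_rows(a: np.ndarray, b: np.ndarray) -> float:
    """Sum of row-wise Pearson correlations between two (G, I) matrices."""
    total = 0.0
    for g in range(a.shape[0]):
        sa, sb = a[g] - a[g].mean(), b[g] - b[g].mean()
        denom = np.sqrt((sa**2).sum() * (sb**2).sum())
        total += float(sa @ sb / denom) if denom > 0 else 0.0
    return total


def _best_perm(ref_beta: np.ndarray, beta: np.ndarray, mu: np.ndarray,
               perms: list[tuple]) -> np.ndarray:
    """Permutation maximizing summed row correlations; ties fall back to mu order."""
    scores = [_pearson_rows(ref_beta, beta[list(p)]) for p in perms]
    best = max(scores)
    cand = [p for p, sc in zip(perms, scores) if sc >= best - 1e-9]
    if len(cand) > 1:  # degenerate: indistinguishable rows; order by mu
        mu_perm = tuple(np.argsort(mu, kind="stable"))
        perm = mu_perm if mu_perm in cand else cand[0]
    else:
        perm = cand[0]
    return np.asarray(perm, dtype=int)


def _apply_perms(s: PosteriorSamples, perms_cd: np.ndarray) -> PosteriorSamples:
    out = PosteriorSamples(
        pi=s.pi.copy(), z=s.z.copy(), beta=s.beta.copy(), theta=s.theta.copy(),
        mu=s.mu.copy(), alpha=s.alpha.copy(), n_chains=s.n_chains,
        n_iter=s.n_iter, n_burnin=s.n_burnin, seed=s.seed, relabeled=True,
    )
    G = s.n_groups
    for c in range(s.n_chains):
        for d in range(s.n_draws):
            perm = perms_cd[c, d]
            inv = np.empty_like(perm)
            inv[perm] = np.arange(G)
            out.pi[c, d] = s.pi[c, d][perm]
            out.beta[c, d] = s.beta[c, d][perm]
            out.mu[c, d] = s.mu[c, d][perm]
            out.alpha[c, d] = s.alpha[c, d][perm]
            out.z[c, d] = inv[s.z[c, d]].astype(out.z.dtype)
    return out


def relabel(s: PosteriorSamples) -> PosteriorSamples:
    """Resolve label switching across draws and chains.

    A mixture posterior is invariant under permutation of group labels; before
    group-specific summaries the draws must share one labeling.  A provisional
    pass aligns every draw with a pivot draw (the first draw of the first
    chain, its groups ordered by mu), which makes the first chain's
    posterior-mean beta a clean reference even when labels switch within a
    chain; the final pass permutes every draw to maximize the summed Pearson
    correlation of its beta rows with that reference.  Exact ties fall back to
    mu order.  Applying relabel twice is a no-op.
    """
    if s.relabeled:
        return s
    G = s.n_groups
    perms = list(itertools.permutations(range(G)))

    pivot_order = np.argsort(s.mu[0, 0], kind="stable")
    pivot_beta = s.beta[0, 0][pivot_order]
    prov = np.empty((s.n_chains, s.n_draws, G), dtype=int)
    for c in range(s.n_chains):
        for d in range(s.n_draws):
            prov[c, d] = _best_perm(pivot_beta, s.beta[c, d], s.mu[c, d], perms)
    provisional = _apply_perms(s, prov)

    ref_order = np.argsort(provisional.mu[0].mean(axis=0), kind="stable")
    ref_beta = provisional.beta[0].mean(axis=0)[ref_order]
    final = np.empty_like(prov)
    for c in range(s.n_chains):
        for d in range(s.n_draws):
            final[c, d] = _best_perm(ref_beta, s.beta[c, d], s.mu[c, d], perms)
    return _apply_perms(s, final)


# --------------------------------------------------------------------------
# assignment
# --------------------------------------------------------------------------

@dataclass
class AssignmentResult:
    """Posterior-mode group per respondent entry, from pooled relabeled draws."""

    modal_group: np.ndarray  # (P,) int, 0-based
    prob: np.ndarray         # (P, G) posterior assignment probabilities
    tie_flag: np.ndarray     # (P,) bool


def assign_groups(s: PosteriorSamples) -> AssignmentResult:
    """Classify each entry by the posterior mode of its group label.

    Pools draws across chains (after relabeling); ties are flagged and broken
    toward the lower group index.
    """
    if not s.relabeled:
        raise ValueError("samples must be relabeled before assignment")
    G = s.n_groups
    flat = s.z.reshape(-1, s.n_entries)  # (C*D, P)
    counts = np.stack([(flat == g).sum(axis=0) for g in range(G)], axis=1)
    prob = counts / counts.sum(axis=1, keepdims=True)
    modal = counts.argmax(axis=1)
    top = counts.max(axis=1, keepdims=True)
    tie = (counts == top).sum(axis=1) > 1
    return AssignmentResult(modal_group=modal, prob=prob, tie_flag=tie)
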