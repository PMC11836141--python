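"""Hierarchical latent-trait Bayesian estimation of individual MPT parameters.

Each participant's parameter vector is theta_i = Phi(mu + delta_i) on the
probit scale, with delta_i ~ N(0, Sigma).  Priors: mu_k ~ N(0, 1); Sigma via
a scaled inverse-Wishart (identity scale, df = K+1) with uniform(0, 10)
scale factors.  Sampling is Metropolis-within-Gibbs with adaptive proposal
scales (inverse-Wishart step for the correlation core is conjugate), run as
multiple independent chains; the contract is the diagnostics (split-chain
R-hat < 1.05, posterior-predictive T1/T2), not the particular sampler.

The posterior-predictive discrepancy statistics are pinned here since the
source analyses name but do not define them:

* T1 -- Pearson-type discrepancy between observed and expected *mean*
  category frequencies: sum over categories of (mean_obs - mean_exp)^2 /
  mean_exp.
* T2 -- summed squared standardized deviations between the observed and
  expected across-participant *covariances* of category frequencies, the
  (j, k) deviation standardized by sqrt(C_exp[j, j] * C_exp[k, k]); the
  expected covariance combines the mean multinomial covariance with the
  between-participant covariance of expected counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr, ndtri

from .errors import DataError, DomainError, SrmptError
from .ml import invert_saturated
from .model import CategoryCounts, ModelSpec, category_probabilities, storage_retrieval_model

__all__ = [
    "LatentTraitConfig",
    "LatentTraitFit",
    "PpcResult",
    "GroupDifference",
    "fit_latent_trait",
    "convergence_check",
    "split_rhat",
    "effective_sample_size",
    "posterior_predictive_check",
    "group_difference",
]

RHAT_THRESHOLD = 1.05


@dataclass
class LatentTraitConfig:
    """Priors and MCMC settings for the latent-trait model."""

    chains: int = 4
    burn_in: int = 2000
    iterations: int = 8000  # retained draws per chain
    thin: int = 1
    seed: int = 0
    mu_prior_sd: float = 1.0
    scale_upper: float = 10.0  # uniform prior bound for Sigma scale factors
    iw_df_extra: int = 1  # inverse-Wishart df = K + iw_df_extra
    adapt_interval: int = 50
    target_accept: tuple[float, float] = (0.2, 0.5)
    lam_sweeps: int = 5  # scale-factor MH sweeps per iteration (each is O(K^2))

    def __post_init__(self):
        if self.chains < 2:
            raise DomainError("need at least 2 chains for R-hat")
        if self.burn_in < 0 or self.iterations < 1 or self.thin < 1:
            raise DomainError("invalid MCMC lengths")


def _as_count_matrix(data, spec: ModelSpec) -> np.ndarray:
    if isinstance(data, np.ndarray):
        mat = np.asarray(data, dtype=float)
    elif isinstance(data, pd.DataFrame):
        from .simulate import CATEGORY_COLUMNS

        labels = [c for t in spec.trees for c in t.categories]
        cols = [CATEGORY_COLUMNS.get(c, c) for c in labels]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise DataError(f"missing category columns: {missing}")
        mat = data[cols].to_numpy(dtype=float)
    elif isinstance(data, (list, tuple)) and data and isinstance(data[0], CategoryCounts):
        mat = np.stack([cc.vector(spec) for cc in data])
    else:
        raise DataError("data must be an (n, categories) array, DataFrame, or CategoryCounts list")
    if mat.ndim != 2:
        raise DataError("count matrix must be two-dimensional")
    return mat


def _tree_slices(spec: ModelSpec) -> list[slice]:
    out, i = [], 0
    for t in spec.trees:
        out.append(slice(i, i + len(t.categories)))
        i += len(t.categories)
    return out


def _make_prob_fn(spec: ModelSpec, param_names: Sequence[str]):
    """Precompile vectorized category probabilities: theta (n, K) -> p (n, C).

    Substitutions are expanded to base-parameter index lists once; a term is
    (index_list, complement) evaluated as prod(theta[:, idx]) or 1 - prod.
    """
    from .model import _expand_substitution

    index = {p: i for i, p in enumerate(param_names)}
    subs = spec.substituted
    compiled = []  # per category: list of branches; branch = list of terms
    for tree in spec.trees:
        per_cat = {c: [] for c in tree.categories}
        for b in tree.branches:
            terms = []
            for t in b.terms:
                idxs = tuple(index[f] for f in _expand_substitution(subs, t.parameter))
                terms.append((idxs, t.complement))
            per_cat[b.category].append(terms)
        for c in tree.categories:
            compiled.append(per_cat[c])

    # generate a single numpy expression per category to avoid interpreted
    # loops in the sampler's hot path
    k = len(param_names)
    header = "def _pm(theta):\n"
    header += "    " + "; ".join(f"t{i} = theta[:, {i}]" for i in range(k)) + "\n"
    col_exprs = []
    for branches in compiled:
        branch_exprs = []
        for terms in branches:
            term_exprs = []
            for idxs, comp in terms:
                prod = "*".join(f"t{i}" for i in idxs)
                term_exprs.append(f"(1.0-{prod})" if comp else f"({prod})")
            branch_exprs.append("*".join(term_exprs))
        col_exprs.append(" + ".join(branch_exprs))
    body = "    return np.stack([" + ", ".join(col_exprs) + "], axis=1)\n"
    namespace: dict = {"np": np}
    exec(header + body, namespace)  # noqa: S102 - generated from validated spec
    return namespace["_pm"]


def _row_loglik(spec: ModelSpec, param_names, counts: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Product-multinomial log-likelihood per participant (constants dropped)."""
    probs = category_probabilities(spec, dict(zip(param_names, theta.T)))
    cols = []
    n = theta.shape[0]
    for tree in spec.trees:
        for c in tree.categories:
            cols.append(np.broadcast_to(probs[tree.name][c], (n,)))
    p = np.clip(np.column_stack(cols), 1e-300, None)
    return np.sum(counts * np.log(p), axis=1)


@dataclass
class PpcResult:
    """Posterior-predictive check of mean (T1) and covariance (T2) structure."""

    t1_observed: float
    t2_observed: float
    p_t1: float
    p_t2: float

    @property
    def satisfactory(self) -> bool:
        return self.p_t1 > 0.05 and self.p_t2 > 0.05


@dataclass
class GroupDifference:
    parameter: str
    groups: tuple[str, str]
    delta_draws: np.ndarray
    bayes_p: float  # posterior mass of (A - B) below zero
    bci: tuple[float, float]

    @property
    def excludes_zero(self) -> bool:
        lo, hi = self.bci
        return lo > 0 or hi < 0


class LatentTraitFit:
    """Posterior draws + summaries from :func:`fit_latent_trait`."""

    def __init__(self, spec, config, counts, param_names, mu_draws, sigma_draws, theta_draws):
        self.spec = spec
        self.config = config
        self.counts = counts
        self.param_names = tuple(param_names)
        self.mu_draws = mu_draws  # (chains, R, K)
        self.sigma_draws = sigma_draws  # (chains, R, K) diagonal of Sigma
        self.theta_draws = theta_draws  # (chains, R_thin, n, K)
        self.rhat = self._compute_rhat()
        self.converged = all(v < RHAT_THRESHOLD for v in self.rhat.values())
        if not self.converged:
            bad = {k: round(v, 4) for k, v in self.rhat.items() if v >= RHAT_THRESHOLD}
            warnings.warn(f"R-hat >= {RHAT_THRESHOLD} for: {bad}", stacklevel=3)
        self.summary = self._summarize()

    def _monitored(self) -> dict[str, np.ndarray]:
        out = {}
        for k, name in enumerate(self.param_names):
            out[f"mu_{name}"] = self.mu_draws[:, :, k]
            out[f"mean_{name}"] = ndtr(self.mu_draws[:, :, k])
            out[f"sigma2_{name}"] = self.sigma_draws[:, :, k]
        return out

    def _compute_rhat(self) -> dict[str, float]:
        return convergence_check(self._monitored())

    def _summarize(self) -> pd.DataFrame:
        rows = []
        for k, name in enumerate(self.param_names):
            draws = ndtr(self.mu_draws[:, :, k]).ravel()
            rows.append(
                {
                    "parameter": name,
                    "mean": float(np.mean(draws)),
                    "median": float(np.median(draws)),
                    "bci_lower": float(np.percentile(draws, 2.5)),
                    "bci_upper": float(np.percentile(draws, 97.5)),
                    "rhat": self.rhat[f"mean_{name}"],
                    "ess": effective_sample_size(ndtr(self.mu_draws[:, :, k])),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def group_prob_draws(self, parameter: str) -> np.ndarray:
        """Pooled draws of the group-level probability Phi(mu_k)."""
        if parameter not in self.param_names:
            raise SrmptError(f"parameter {parameter!r} not monitored")
        k = self.param_names.index(parameter)
        return ndtr(self.mu_draws[:, :, k]).ravel()

    @property
    def n_retained(self) -> int:
        return self.mu_draws.shape[0] * self.mu_draws.shape[1]


def fit_latent_trait(
    spec: ModelSpec | None,
    data,
    config: LatentTraitConfig | None = None,
) -> LatentTraitFit:
    """Sample the posterior of the latent-trait model for one condition.

    ``data`` holds one participant per row: category counts in the spec's
    canonical order (ndarray), the participant-table columns (DataFrame), or
    a list of :class:`CategoryCounts`.
    """
    spec = spec or storage_retrieval_model()
    config = config or LatentTraitConfig()
    counts = _as_count_matrix(data, spec)
    n = counts.shape[0]
    if n < 2:
        raise DataError("need at least 2 participants")
    param_names = spec.base_parameters
    K = len(param_names)

    mu_init = _initial_mu(spec, counts, K)
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    mu_chains, sigma_chains, theta_chains = [], [], []
    for seq in seeds:
        mu_d, sig_d, th_d = _run_chain(
            spec, param_names, counts, config, mu_init, np.random.default_rng(seq)
        )
        mu_chains.append(mu_d)
        sigma_chains.append(sig_d)
        theta_chains.append(th_d)
    return LatentTraitFit(
        spec,
        config,
        counts,
        param_names,
        np.stack(mu_chains),
        np.stack(sigma_chains),
        np.stack(theta_chains),
    )


def _initial_mu(spec: ModelSpec, counts: np.ndarray, K: int) -> np.ndarray:
    pooled = CategoryCounts.from_vector(spec, counts.sum(axis=0))
    try:
        est = invert_saturated(pooled)
        probs = [est[p] for p in spec.base_parameters]
    except Exception:
        probs = [0.5] * K
    return ndtri(np.clip(probs, 0.02, 0.98))


def _run_chain(spec, param_names, counts, config, mu_init, rng):
    n, K = counts.shape[0], len(param_names)
    prob_fn = _make_prob_fn(spec, param_names)

    def _row_loglik_fast(theta):
        p = np.clip(prob_fn(theta), 1e-300, None)
        return np.sum(counts * np.log(p), axis=1)
    mu = mu_init + 0.3 * rng.standard_normal(K)
    delta = np.zeros((n, K))
    # overdispersed scale inits so chains approach Sigma from different sides
    lam = rng.uniform(0.1, 0.9, K) * config.scale_upper
    Q = np.eye(K)
    q_chol = np.linalg.cholesky(Q)
    sigma = (lam[:, None] * Q) * lam[None, :]
    sigma_inv = np.linalg.inv(sigma)

    theta = ndtr(mu + delta)
    ll = _row_loglik_fast(theta)

    step_delta = np.full(n, 0.4)
    step_mu = np.full(K, 0.15)
    step_lam = np.full(K, 0.4)
    acc_delta = np.zeros(n)
    acc_mu = np.zeros(K)
    acc_lam = np.zeros(K)
    step_anc = np.full(K, 0.4)
    acc_anc = np.zeros(K)
    mu_hist = np.empty((max(config.burn_in, 1), K))
    mu_chol = None
    step_joint = 0.7
    acc_joint = 0.0
    lo, hi = config.target_accept

    total = config.burn_in + config.iterations * config.thin
    R = config.iterations
    mu_draws = np.empty((R, K))
    sigma_draws = np.empty((R, K))
    theta_draws = np.empty((R, n, K))
    kept = 0
    iw_df = K + config.iw_df_extra + n

    for it in range(total):
        # --- individual deviations (vectorized random-walk MH) ---
        # proposals shaped by chol(Sigma): the per-parameter prior scales can
        # differ by orders of magnitude, so isotropic steps mix poorly
        sigma_chol = np.linalg.cholesky(sigma + 1e-12 * np.eye(K))
        prop = delta + step_delta[:, None] * (rng.standard_normal((n, K)) @ sigma_chol.T)
        theta_prop = ndtr(mu + prop)
        ll_prop = _row_loglik_fast(theta_prop)
        lp_cur = -0.5 * np.einsum("ij,jk,ik->i", delta, sigma_inv, delta)
        lp_prop = -0.5 * np.einsum("ij,jk,ik->i", prop, sigma_inv, prop)
        accept = np.log(rng.uniform(size=n)) < (ll_prop + lp_prop) - (ll + lp_cur)
        delta[accept] = prop[accept]
        theta[accept] = theta_prop[accept]
        ll[accept] = ll_prop[accept]
        acc_delta += accept

        # --- group means (componentwise MH) ---
        for k in range(K):
            mu_k = mu[k] + step_mu[k] * rng.standard_normal()
            mu_prop = mu.copy()
            mu_prop[k] = mu_k
            theta_prop = ndtr(mu_prop + delta)
            ll_prop = _row_loglik_fast(theta_prop)
            d_prior = -0.5 * (mu_k**2 - mu[k] ** 2) / config.mu_prior_sd**2
            if np.log(rng.uniform()) < float(np.sum(ll_prop - ll)) + d_prior:
                mu = mu_prop
                theta = theta_prop
                ll = ll_prop
                acc_mu[k] += 1

        # --- joint group-mean update along the adapted covariance ---
        # componentwise moves cannot follow likelihood ridges (e.g. the
        # s*r2 trade-off), so a block proposal shaped by the empirical
        # covariance of mu (learned during burn-in) is added
        if mu_chol is not None:
            mu_prop = mu + step_joint * (mu_chol @ rng.standard_normal(K))
            theta_prop = ndtr(mu_prop + delta)
            ll_prop = _row_loglik_fast(theta_prop)
            d_prior = -0.5 * float(mu_prop @ mu_prop - mu @ mu) / config.mu_prior_sd**2
            if np.log(rng.uniform()) < float(np.sum(ll_prop - ll)) + d_prior:
                mu = mu_prop
                theta = theta_prop
                ll = ll_prop
                acc_joint += 1
        if it < config.burn_in:
            mu_hist[it] = mu
            if (it + 1) % config.adapt_interval == 0 and it + 1 >= 2 * config.adapt_interval:
                emp = np.cov(mu_hist[: it + 1].T) + 1e-8 * np.eye(K)
                mu_chol = np.linalg.cholesky(emp)
                if acc_joint / config.adapt_interval > hi:
                    step_joint *= 1.25
                elif acc_joint / config.adapt_interval < lo:
                    step_joint /= 1.25
                acc_joint = 0.0

        # --- interweaving step: conjugate redraw of mu given xi = mu + delta ---
        # theta depends on xi only, so redrawing mu from its exact conditional
        # N(m, V) with V = (n Sigma^-1 + I/sd^2)^-1 and shifting delta to keep
        # xi fixed leaves the likelihood untouched while breaking the
        # mu/delta translation degeneracy that otherwise stalls mixing.
        xi_bar = mu + delta.mean(axis=0)
        prec = n * sigma_inv + np.eye(K) / config.mu_prior_sd**2
        cov_mu = np.linalg.inv(prec)
        m = cov_mu @ (n * (sigma_inv @ xi_bar))
        mu_new = m + np.linalg.cholesky(cov_mu) @ rng.standard_normal(K)
        delta = delta + (mu - mu_new)
        mu = mu_new

        # --- correlation core of Sigma (conjugate inverse-Wishart) ---
        eta = delta / lam
        psi = np.eye(K) + eta.T @ eta
        for _ in range(5):
            Q_new = stats.invwishart.rvs(df=iw_df, scale=psi, random_state=rng)
            try:
                q_chol = np.linalg.cholesky(Q_new)
                Q = Q_new
                break
            except np.linalg.LinAlgError:
                psi = psi + 1e-8 * np.eye(K)  # resampling guard

        # --- scale factors (log-scale MH, uniform(0, upper) prior) ---
        # log p(delta | lam, Q) reduces to -0.5 tr(Q^-1 S / lam lam^T)
        # - n sum(log lam) + const with S = delta^T delta, so each proposal
        # costs O(K^2) instead of O(n K^2)
        scatter = delta.T @ delta
        q_inv = np.linalg.inv(Q)

        def _lam_logpost(values: np.ndarray) -> float:
            quad = float(np.sum(q_inv * (scatter / np.outer(values, values))))
            return -0.5 * quad - n * float(np.sum(np.log(values)))

        lp_cur_total = _lam_logpost(lam)
        for sweep in range(config.lam_sweeps):
            for k in range(K):
                lam_k = lam[k] * np.exp(step_lam[k] * rng.standard_normal())
                if lam_k >= config.scale_upper:
                    continue
                lam_prop = lam.copy()
                lam_prop[k] = lam_k
                lp_prop_total = _lam_logpost(lam_prop)
                # + log-Jacobian of the log-scale proposal
                if np.log(rng.uniform()) < lp_prop_total - lp_cur_total + np.log(lam_k / lam[k]):
                    lam = lam_prop
                    lp_cur_total = lp_prop_total
                    if sweep == 0:
                        acc_lam[k] += 1
        # --- ancillary-scale interweave on lambda ---
        # holding eta = delta/lambda fixed (prior N(0, Q), independent of
        # lambda) and rescaling delta with the proposed lambda lets the
        # heterogeneity scale grow or shrink with the deviations following,
        # which breaks the small-Sigma/small-delta vicious circle
        for k in range(K):
            lam_k = lam[k] * np.exp(step_anc[k] * rng.standard_normal())
            if lam_k >= config.scale_upper:
                continue
            delta_prop = delta.copy()
            delta_prop[:, k] *= lam_k / lam[k]
            theta_prop = ndtr(mu + delta_prop)
            ll_prop = _row_loglik_fast(theta_prop)
            # flat prior in lambda; log-scale proposal Jacobian lam'/lam
            if np.log(rng.uniform()) < float(np.sum(ll_prop - ll)) + np.log(lam_k / lam[k]):
                lam = lam.copy()
                lam[k] = lam_k
                delta = delta_prop
                theta = theta_prop
                ll = ll_prop
                acc_anc[k] += 1

        sigma = (lam[:, None] * Q) * lam[None, :]
        sigma_inv = np.linalg.inv(sigma)

        # --- adaptation during burn-in ---
        if it < config.burn_in and (it + 1) % config.adapt_interval == 0:
            w = config.adapt_interval
            for steps, acc in (
                (step_delta, acc_delta),
                (step_mu, acc_mu),
                (step_lam, acc_lam),
                (step_anc, acc_anc),
            ):
                rate = acc / w
                steps[rate > hi] *= 1.25
                steps[rate < lo] /= 1.25
                acc[:] = 0.0

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            mu_draws[kept] = mu
            sigma_draws[kept] = np.diag(sigma)
            theta_draws[kept] = theta
            kept += 1
    return mu_draws, sigma_draws, theta_draws


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def split_rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one scalar quantity.

    ``draws`` has shape (chains, iterations); each chain is split in half.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise SrmptError("R-hat needs at least 2 chains of equal length")
    m, length = draws.shape
    half = length // 2
    if half < 2:
        raise SrmptError("chains too short for split R-hat")
    halves = np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)
    within = halves.var(axis=1, ddof=1).mean()
    between = half * halves.mean(axis=1).var(ddof=1)
    if within == 0:
        return 1.0
    var_plus = (half - 1) / half * within + between / half
    return float(np.sqrt(var_plus / within))


def convergence_check(draws: Mapping[str, np.ndarray]) -> dict[str, float]:
    """Split-chain R-hat per monitored scalar quantity."""
    return {name: split_rhat(arr) for name, arr in draws.items()}


def effective_sample_size(draws: np.ndarray, max_lag: int | None = None) -> float:
    """Crude autocorrelation-based ESS pooled over chains (initial positive sequence)."""
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    m, length = draws.shape
    if length < 4:
        return float(m * length)
    max_lag = max_lag or min(length - 2, 1000)
    centered = draws - draws.mean(axis=1, keepdims=True)
    denom = np.sum(centered**2)
    if denom == 0:
        return float(m * length)
    rho_sum = 0.0
    for lag in range(1, max_lag):
        rho = np.sum(centered[:, :-lag] * centered[:, lag:]) / denom
        if rho <= 0:
            break
        rho_sum += rho
    return float(m * length / (1.0 + 2.0 * rho_sum))


# ---------------------------------------------------------------------------
# posterior-predictive checks
# ---------------------------------------------------------------------------

def _expected_cov(p: np.ndarray, totals: np.ndarray, slices) -> np.ndarray:
    """Expected across-participant covariance of category counts.

    Mean multinomial covariance (block-diagonal over trees) plus the
    covariance of the expected count vectors across participants.
    """
    n, c = p.shape
    e = p * totals
    cov = np.cov(e.T, ddof=1)
    for sl, tot in zip(slices, _tree_totals(totals, slices)):
        pb = p[:, sl]
        block = tot * (np.einsum("ij,ik->jk", pb, -pb) / n)
        block += tot * np.diag(pb.mean(axis=0))
        cov[sl, sl] += block
    return cov


def _tree_totals(totals: np.ndarray, slices) -> list[float]:
    return [float(totals[sl][0]) for sl in slices]


def _t1(observed_mean, expected_mean) -> float:
    e = np.clip(expected_mean, 1e-12, None)
    return float(np.sum((observed_mean - e) ** 2 / e))


def _t2(observed_cov, expected_cov) -> float:
    # squared deviations standardized by sqrt(C_exp[j,j] * C_exp[k,k]), squared
    scale = np.clip(np.outer(np.diag(expected_cov), np.diag(expected_cov)), 1e-12, None)
    dev = (observed_cov - expected_cov) ** 2 / scale
    iu = np.triu_indices_from(dev)
    return float(np.sum(dev[iu]))


def posterior_predictive_check(
    fit: LatentTraitFit, n_rep: int = 500, seed: int | None = 0
) -> PpcResult:
    """PPC of T1 (means) and T2 (covariances) over ``n_rep`` retained draws."""
    if n_rep < 100:
        warnings.warn("n_rep < 100 gives unstable posterior-predictive p-values", stacklevel=2)
    chains, R, n, K = fit.theta_draws.shape
    total = chains * R
    if total < n_rep:
        raise SrmptError(f"only {total} retained draws, need n_rep={n_rep}")
    rng = np.random.default_rng(seed)
    theta_flat = fit.theta_draws.reshape(total, n, K)
    idx = np.linspace(0, total - 1, n_rep).astype(int)
    spec = fit.spec
    slices = _tree_slices(spec)
    counts = fit.counts
    totals = counts[0].copy()
    for sl in slices:
        totals[sl] = counts[0, sl].sum()
    obs_mean = counts.mean(axis=0)
    obs_cov = np.cov(counts.T, ddof=1)

    t1_obs = np.empty(n_rep)
    t1_rep = np.empty(n_rep)
    t2_obs = np.empty(n_rep)
    t2_rep = np.empty(n_rep)
    tree_totals = _tree_totals(totals, slices)
    for j, ix in enumerate(idx):
        theta = theta_flat[ix]
        probs = category_probabilities(spec, dict(zip(fit.param_names, theta.T)))
        cols = []
        for tree in spec.trees:
            for cat in tree.categories:
                cols.append(np.broadcast_to(probs[tree.name][cat], (n,)))
        p = np.column_stack(cols)
        e_mean = (p * totals).mean(axis=0)
        e_cov = _expected_cov(p, totals, slices)
        rep = np.empty_like(counts)
        for sl, tot in zip(slices, tree_totals):
            pb = p[:, sl]
            pb = pb / pb.sum(axis=1, keepdims=True)
            for i in range(n):
                rep[i, sl] = rng.multinomial(int(tot), pb[i])
        t1_obs[j] = _t1(obs_mean, e_mean)
        t1_rep[j] = _t1(rep.mean(axis=0), e_mean)
        t2_obs[j] = _t2(obs_cov, e_cov)
        t2_rep[j] = _t2(np.cov(rep.T, ddof=1), e_cov)
    return PpcResult(
        t1_observed=float(t1_obs.mean()),
        t2_observed=float(t2_obs.mean()),
        p_t1=float(np.mean(t1_rep >= t1_obs)),
        p_t2=float(np.mean(t2_rep >= t2_obs)),
    )


def group_difference(
    post_a: LatentTraitFit,
    post_b: LatentTraitFit,
    parameter: str,
    names: tuple[str, str] = ("A", "B"),
) -> GroupDifference:
    """Posterior of the group-level difference Phi(mu_A) - Phi(mu_B).

    Draws are paired by index after truncation to equal length (the fits are
    independent, so any pairing is valid; index pairing is reproducible).
    The one-tailed Bayesian p is the posterior mass below zero.
    """
    a = post_a.group_prob_draws(parameter)
    b = post_b.group_prob_draws(parameter)
    length = min(a.size, b.size)
    d = a[:length] - b[:length]
    # ties (measure zero for real posteriors) split evenly so that
    # identical draw sequences give p = 0.5
    return GroupDifference(
        parameter=parameter,
        groups=names,
        delta_draws=d,
        bayes_p=float(np.mean(d < 0) + 0.5 * np.mean(d == 0)),
        bci=(float(np.percentile(d, 2.5)), float(np.percentile(d, 97.5))),
    )
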