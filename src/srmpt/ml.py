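"""Maximum-likelihood inference for (multi-group) MPT models.

Fitting maximizes the product-multinomial log-likelihood over the free
parameters on a logit-transformed scale with an analytic gradient and a
seeded multi-start strategy.  Goodness of fit is the likelihood-ratio
statistic G^2; nested model versions are compared via Delta G^2, with
``z = sqrt(Delta G^2)`` for single-df one-tailed hypotheses.  A closed-form
inversion of the saturated storage-retrieval model is provided as an
independent check on the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit

from .errors import (
    ConvergenceError,
    DataError,
    DomainError,
    InversionError,
    SrmptError,
)
from .model import (
    CategoryCounts,
    Constraint,
    ConstrainedModel,
    DfAccount,
    ModelSpec,
    build_constrained,
)

__all__ = [
    "MlFitResult",
    "ModelComparison",
    "ConfidenceInterval",
    "fit_ml",
    "goodness_of_fit",
    "compare_nested",
    "wald_ci",
    "profile_ci",
    "invert_saturated",
    "g_squared",
]

_BOUNDARY_EPS = 1e-6


def g_squared(observed: np.ndarray, expected: np.ndarray) -> float:
    """Likelihood-ratio statistic 2 * sum n * log(n / e) with 0*log0 = 0."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    mask = observed > 0
    return float(
        2.0 * np.sum(observed[mask] * np.log(observed[mask] / expected[mask]))
    )


@dataclass
class MlFitResult:
    """Result of an ML fit: estimates, fit statistic, and diagnostics."""

    model: ConstrainedModel
    estimates: dict  # group -> {parameter -> value}, substitutions resolved
    theta: np.ndarray  # free-parameter values (probability scale)
    loglik: float
    g2: float
    df_account: DfAccount
    converged: bool
    covariance: np.ndarray | None  # free-parameter covariance, None if singular
    n_restarts: int
    counts: dict  # group -> CategoryCounts
    boundary: bool = False

    @property
    def df(self) -> int:
        return self.df_account.df

    @property
    def p_value(self) -> float | None:
        """Goodness-of-fit p; ``None`` for df = 0 (identifiable, not testable)."""
        if self.df <= 0:
            return None
        return float(stats.chi2.sf(self.g2, self.df))

    @property
    def free_names(self) -> tuple:
        return self.model.free_names

    def constraint_set(self) -> frozenset:
        return frozenset(self.model.spec.constraints)


def _loglik_and_grad(model: ConstrainedModel, n: np.ndarray, x: np.ndarray):
    """Log-likelihood and gradient w.r.t. logit-scale free parameters."""
    theta = expit(x)
    p = np.clip(model.prob_vector(theta), 1e-300, None)
    ll = float(np.sum(n * np.log(p)))
    J = model.jacobian(theta)  # d p / d theta
    grad_theta = J.T @ (n / p)
    grad_x = grad_theta * theta * (1.0 - theta)
    return ll, grad_x


def fit_ml(
    spec: ModelSpec,
    counts,
    groups: Sequence[str | None] | None = None,
    constraints: Iterable[Constraint | str] = (),
    restarts: int = 10,
    seed: int | None = 0,
    tol: float = 1e-12,
    start: Mapping | None = None,
) -> MlFitResult:
    """Fit an MPT model to aggregated category frequencies by ML.

    ``counts`` is a single :class:`CategoryCounts` (one group) or a mapping
    group name -> CategoryCounts.  Extra ``constraints`` are merged into the
    spec's constraint set before compilation.  ``start`` optionally provides
    per-group parameter values used as the first optimizer start.
    """
    if isinstance(counts, CategoryCounts):
        counts_by_group = {None: counts}
        if groups is None:
            groups = (None,)
    else:
        counts_by_group = dict(counts)
        if groups is None:
            groups = tuple(counts_by_group)
    model = build_constrained(spec, groups, constraints)
    n = model.counts_vector(counts_by_group)
    # per-(group, tree) totals, aligned with the flat output layout
    totals = np.empty_like(n)
    i = 0
    for grp in model.groups:
        for tree in model.spec.trees:
            k = len(tree.categories)
            block = n[i : i + k]
            if block.sum() <= 0:
                raise DataError(f"all counts zero in tree {tree.name!r} (group {grp!r})")
            totals[i : i + k] = block.sum()
            i += k

    rng = np.random.default_rng(seed)
    starts = []
    if start is not None:
        starts.append(logit(np.clip(model.theta_from_parameters(start), 1e-4, 1 - 1e-4)))
    starts.append(np.zeros(model.n_free))
    while len(starts) < max(restarts, 1):
        starts.append(logit(rng.uniform(0.05, 0.95, size=model.n_free)))

    def neg_objective(x):
        ll, grad = _loglik_and_grad(model, n, x)
        return -ll, -grad

    best_x, best_ll, best_ok = None, -np.inf, False
    for x0 in starts:
        res = optimize.minimize(
            neg_objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": tol, "gtol": 1e-10},
        )
        if -res.fun > best_ll:
            best_ll, best_x, best_ok = -res.fun, res.x, bool(res.success)
    if best_x is None:
        raise ConvergenceError("optimizer failed on every restart")

    theta = expit(best_x)
    p_hat = model.prob_vector(theta)
    g2 = g_squared(n, totals * np.clip(p_hat, 1e-300, None))
    boundary = bool(np.any(theta < _BOUNDARY_EPS) or np.any(theta > 1 - _BOUNDARY_EPS))
    cov = _observed_info_covariance(model, n, theta) if not boundary else None
    return MlFitResult(
        model=model,
        estimates=model.parameter_values(theta),
        theta=theta,
        loglik=best_ll,
        g2=max(g2, 0.0),
        df_account=model.df_account(),
        converged=best_ok,
        covariance=cov,
        n_restarts=len(starts),
        counts=counts_by_group,
        boundary=boundary,
    )


def _observed_info_covariance(
    model: ConstrainedModel, n: np.ndarray, theta: np.ndarray, h: float = 1e-5
) -> np.ndarray | None:
    """Inverse observed information on the probability scale (central differences)."""

    def grad(t: np.ndarray) -> np.ndarray:
        p = np.clip(model.prob_vector(t), 1e-300, None)
        return model.jacobian(t).T @ (n / p)

    k = model.n_free
    H = np.empty((k, k))
    for j in range(k):
        tp, tm = theta.copy(), theta.copy()
        tp[j] = min(tp[j] + h, 1 - 1e-9)
        tm[j] = max(tm[j] - h, 1e-9)
        H[:, j] = (grad(tp) - grad(tm)) / (tp[j] - tm[j])
    H = 0.5 * (H + H.T)
    info = -H
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return None
    if np.any(np.diag(cov) < 0):
        return None
    return cov


def goodness_of_fit(fit: MlFitResult) -> tuple[float, int, float | None]:
    """(G^2, df, p).  ``p`` is ``None`` when df = 0."""
    return fit.g2, fit.df, fit.p_value


@dataclass(frozen=True)
class ModelComparison:
    """Nested-model likelihood-ratio comparison."""

    delta_g2: float
    delta_df: int
    p_two_tailed: float
    z: float | None  # sqrt(Delta G^2), only when delta_df == 1
    p_one_tailed: float | None
    direction_matches: bool | None

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_two_tailed < alpha


def compare_nested(
    general: MlFitResult,
    restricted: MlFitResult,
    tail: str = "two",
    direction: tuple | None = None,
) -> ModelComparison:
    """Compare nested fits on the same data via Delta G^2.

    ``direction`` names the hypothesized ordering for one-tailed tests as
    ``(parameter, larger_group, smaller_group)``; the observed ordering is
    taken from the *general* fit.  A mismatch between hypothesis and data
    yields p > 0.5, never reflected significance.
    """
    if not (general.constraint_set() <= restricted.constraint_set()):
        raise SrmptError(
            "restricted model's constraint set must contain the general model's"
        )
    if set(general.model.groups) != set(restricted.model.groups) or any(
        general.counts[g] != restricted.counts[g] for g in general.model.groups
    ):
        raise SrmptError("nested comparison requires identical data")
    delta_g2 = restricted.g2 - general.g2
    if delta_g2 < -1e-6:
        raise ConvergenceError(
            f"restricted fit beats general fit (Delta G^2 = {delta_g2:.3g}); "
            "re-run with more restarts"
        )
    delta_g2 = max(delta_g2, 0.0)
    delta_df = restricted.df - general.df
    if delta_df < 0:
        raise SrmptError("restricted model has more free parameters than the general one")
    if delta_df == 0:
        # identical effective constraint sets: no test, Delta G^2 degenerates to 0
        return ModelComparison(delta_g2, 0, 1.0, None, None, None)
    p_two = float(stats.chi2.sf(delta_g2, delta_df))
    z = float(np.sqrt(delta_g2)) if delta_df == 1 else None
    p_one = None
    matches = None
    if tail == "one":
        if delta_df != 1 or direction is None:
            raise SrmptError(
                "one-tailed comparison requires delta_df == 1 and a direction "
                "(parameter, larger_group, smaller_group)"
            )
        param, larger, smaller = direction
        observed = (
            general.estimates[larger][param] - general.estimates[smaller][param]
        )
        matches = observed >= 0
        p_one = p_two / 2.0 if matches else 1.0 - p_two / 2.0
    return ModelComparison(delta_g2, delta_df, p_two, z, p_one, matches)


@dataclass(frozen=True)
class ConfidenceInterval:
    parameter: str
    group: str | None
    level: float
    estimate: float
    lower: float | None
    upper: float | None

    @property
    def missing(self) -> bool:
        return self.lower is None


def wald_ci(fit: MlFitResult, level: float = 0.95) -> list[ConfidenceInterval]:
    """Wald intervals on the probability scale, clipped to [0, 1].

    Boundary fits or a singular information matrix yield flagged (missing)
    intervals rather than a failure.
    """
    z = stats.norm.ppf(0.5 + level / 2.0)
    out = []
    for i, (param, grp) in enumerate(fit.free_names):
        est = float(fit.theta[i])
        if fit.covariance is None:
            out.append(ConfidenceInterval(param, grp, level, est, None, None))
            continue
        se = float(np.sqrt(fit.covariance[i, i]))
        lo = float(np.clip(est - z * se, 0.0, 1.0))
        hi = float(np.clip(est + z * se, 0.0, 1.0))
        out.append(ConfidenceInterval(param, grp, level, est, lo, hi))
    return out


def profile_ci(
    spec: ModelSpec,
    fit: MlFitResult,
    parameter: str,
    group: str | None = None,
    level: float = 0.95,
    constraints: Iterable[Constraint | str] = (),
) -> ConfidenceInterval:
    """Profile-likelihood interval for one free parameter.

    Finds the values where the profiled likelihood drops by the chi-square(1)
    quantile, refitting the remaining free parameters at each probe.  Slower
    than :func:`wald_ci` but boundary-respecting.
    """
    from .model import Fix

    try:
        i = fit.free_names.index((parameter, group))
    except ValueError as exc:
        raise SrmptError(f"{parameter!r} (group {group!r}) is not a free parameter") from exc
    estimate = float(fit.theta[i])
    threshold = float(stats.chi2.isf(1.0 - level, 1))
    base_spec = fit.model.spec if not constraints else fit.model.spec.with_constraints(constraints)

    def deficit(value: float) -> float:
        fixed = fit_ml(
            base_spec,
            fit.counts,
            groups=fit.model.groups,
            constraints=[Fix(parameter, value, group)],
            restarts=1,
            seed=0,
            start=fit.estimates,
        )
        return 2.0 * (fit.loglik - fixed.loglik) - threshold

    def solve(lo: float, hi: float) -> float | None:
        try:
            return float(optimize.brentq(deficit, lo, hi, xtol=1e-5))
        except ValueError:
            return None

    eps = 1e-6
    lower = solve(eps, estimate - eps) if deficit(eps) > 0 else 0.0
    upper = solve(estimate + eps, 1 - eps) if deficit(1 - eps) > 0 else 1.0
    return ConfidenceInterval(parameter, group, level, estimate, lower, upper)


# ---------------------------------------------------------------------------
# closed-form saturated inversion (independent of the optimizer)
# ---------------------------------------------------------------------------

def invert_saturated(counts: CategoryCounts) -> dict[str, float]:
    """Algebraic ML solution of the saturated storage-retrieval model.

    With observed relative frequencies h = P(Rn+), fa = P(D-), c = P(Rc+) and
    q3 = P(Rn-Rc+):

        s*r1 = h - fa
        g    = fa / (1 - (h - fa))
        s    = (h - fa) * (1 - g) * c / ((1 - g) * c - q3)
        r2   = c / s,  r1 = (h - fa) / s

    Defined only for interior data with above-chance memory (h > fa).
    """
    t = counts.counts.get("target")
    d = counts.counts.get("distractor")
    if t is None or d is None:
        raise DataError("counts must contain 'target' and 'distractor' trees")
    n_t = sum(t.values())
    n_d = sum(d.values())
    if n_t <= 0 or n_d <= 0:
        raise DataError("empty tree")
    h = (t.get("Rn+Rc+", 0) + t.get("Rn+Rc-", 0)) / n_t
    c = (t.get("Rn+Rc+", 0) + t.get("Rn-Rc+", 0)) / n_t
    q3 = t.get("Rn-Rc+", 0) / n_t
    fa = d.get("D-", 0) / n_d
    a = h - fa  # = s*r1
    if a <= 0:
        raise InversionError(f"hit rate ({h:.4g}) not above false-alarm rate ({fa:.4g})")
    if 1.0 - a <= 0:
        raise InversionError("s*r1 estimate at 1; guessing parameter undefined")
    g = fa / (1.0 - a)
    if g >= 1.0:
        raise InversionError("guessing estimate at or above 1")
    denom = (1.0 - g) * c - q3
    if denom <= 0:
        raise InversionError("storage estimate undefined (degenerate frequencies)")
    s = a * (1.0 - g) * c / denom
    if not 0 < s <= 1:
        raise InversionError(f"storage estimate {s:.4g} outside (0, 1]")
    r1 = a / s
    r2 = c / s
    for name, v in (("r1", r1), ("r2", r2)):
        if not 0 <= v <= 1:
            raise InversionError(f"{name} estimate {v:.4g} outside [0, 1]")
    return {"s": s, "r1": r1, "g": g, "r2": r2}
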