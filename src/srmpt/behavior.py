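"""Behavioral scores, outlier screening, ANOVA/contrasts, and power analysis.

Scores follow the study's definitions: recall retention = delayed correct /
immediate correct (from the cycle in which the learning criterion was
reached; values above 1 are possible), recognition performance = hit rate -
false-alarm rate.  Outliers are flagged per session when either score lies
more than ``multiplier`` median absolute deviations from the pooled grand
median.  Sample sizes come from the noncentral-F power function of the
one-way between-participants ANOVA.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DomainError, SrmptError
from .simulate import CATEGORY_COLUMNS

__all__ = [
    "OutlierRule",
    "AnovaResult",
    "ContrastResult",
    "DesignSpec",
    "score_participants",
    "mad_outliers",
    "apply_exclusions",
    "oneway_anova",
    "planned_contrast",
    "anova_power",
    "required_sample_size",
    "oversampled_n",
]


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_participants(records: pd.DataFrame, n_items: int = 20) -> pd.DataFrame:
    """Per-participant/session behavioral scores.

    Expects the participant-table schema (category-count columns ``RnpRcp``
    ... ``Dm`` plus ``immediate_correct``).  Criterion failures (``excluded``
    truthy) are marked ``excluded_at_source`` and receive no scores.
    """
    df = records.copy()
    missing = [c for c in list(CATEGORY_COLUMNS.values()) + ["immediate_correct"] if c not in df.columns]
    if missing:
        raise DataError(f"missing columns: {missing}")
    source_excluded = (
        df["excluded"].astype(bool) if "excluded" in df.columns else pd.Series(False, index=df.index)
    )
    immediate = df["immediate_correct"].astype(float)
    if ((immediate <= 0) & ~source_excluded).any():
        raise DataError("immediate correct count of 0 for an included participant")
    delayed = df["RnpRcp"] + df["RnmRcp"]
    hits = (df["RnpRcp"] + df["RnpRcm"]) / n_items
    fas = df["Dm"] / n_items
    out = df[[c for c in ("id", "condition", "session") if c in df.columns]].copy()
    out["immediate_correct"] = immediate
    out["delayed_correct"] = delayed.astype(float)
    out["retention"] = delayed / immediate
    out["hit_rate"] = hits
    out["false_alarm_rate"] = fas
    out["recognition"] = hits - fas
    out["excluded_at_source"] = source_excluded.to_numpy()
    out.loc[source_excluded, ["retention", "recognition"]] = np.nan
    return out


# ---------------------------------------------------------------------------
# outlier rule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutlierRule:
    """MAD-based screening rule.

    ``scaled`` applies the 1.4826 normal-consistency constant to the MAD
    (the unscaled variant is available because the study's wording does not
    pin the convention down).
    """

    multiplier: float = 3.0
    scaled: bool = True
    variables: tuple[str, ...] = ("retention", "recognition")

    def __post_init__(self):
        if self.multiplier <= 0:
            raise DomainError("multiplier must be positive")


def mad_outliers(values, rule: OutlierRule = OutlierRule()) -> np.ndarray:
    """Flag x with |x - median| > multiplier * MAD(values); NaNs never flag."""
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size < 3:
        raise DataError("need at least 3 values for MAD screening")
    med = float(np.median(finite))
    scale = "normal" if rule.scaled else 1.0
    mad = float(stats.median_abs_deviation(finite, scale=scale))
    if mad == 0:
        warnings.warn("MAD is zero; no outliers flagged", stacklevel=2)
        return np.zeros(values.shape, dtype=bool)
    with np.errstate(invalid="ignore"):
        return np.abs(values - med) > rule.multiplier * mad


def apply_exclusions(scores: pd.DataFrame, rule: OutlierRule = OutlierRule()) -> pd.DataFrame:
    """Per-session MAD screening on each score; union rule across scores.

    Grand medians pool all conditions within a session, so flags are
    invariant to condition labels.  Adds boolean columns ``outlier_<var>``
    and ``excluded`` (source exclusions propagate).
    """
    df = scores.copy()
    sessions = df["session"].unique() if "session" in df.columns else [None]
    for var in rule.variables:
        df[f"outlier_{var}"] = False
        for ses in sessions:
            mask = (df["session"] == ses) if ses is not None else pd.Series(True, index=df.index)
            flags = mad_outliers(df.loc[mask, var].to_numpy(), rule)
            df.loc[mask, f"outlier_{var}"] = flags
    union = np.zeros(len(df), dtype=bool)
    for var in rule.variables:
        union |= df[f"outlier_{var}"].to_numpy()
    if "excluded_at_source" in df.columns:
        union |= df["excluded_at_source"].to_numpy()
    df["excluded"] = union
    return df


# ---------------------------------------------------------------------------
# ANOVA + planned contrasts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    f: float
    df1: int
    df2: int
    p: float
    eta_squared: float
    ms_error: float
    group_means: dict
    group_ns: dict


@dataclass(frozen=True)
class ContrastResult:
    weights: dict
    estimate: float
    t: float
    df: int
    p: float
    tail: str
    cohens_d: float | None


def _split_groups(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups.tolist()))
    data = {g: values[groups == g] for g in labels}
    for g, v in data.items():
        if v.size < 2:
            raise DataError(f"group {g!r} has fewer than 2 observations")
    return labels, data


def oneway_anova(values, groups) -> AnovaResult:
    """One-factorial between-participants ANOVA with eta-squared."""
    labels, data = _split_groups(values, groups)
    if len(labels) < 2:
        raise DataError("need at least 2 groups")
    all_values = np.concatenate([data[g] for g in labels])
    grand = all_values.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in data.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    df1 = len(labels) - 1
    df2 = all_values.size - len(labels)
    if ss_within <= 0:
        raise DataError("zero residual variance")
    ms_error = ss_within / df2
    f = (ss_between / df1) / ms_error
    p = float(stats.f.sf(f, df1, df2))
    eta2 = ss_between / (ss_between + ss_within)
    return AnovaResult(
        f=float(f),
        df1=df1,
        df2=df2,
        p=p,
        eta_squared=float(eta2),
        ms_error=float(ms_error),
        group_means={g: float(v.mean()) for g, v in data.items()},
        group_ns={g: int(v.size) for g, v in data.items()},
    )


def planned_contrast(
    values,
    groups,
    weights: dict,
    tail: str = "two",
    direction: str | None = None,
) -> ContrastResult:
    """Planned contrast using the pooled error term of the full ANOVA.

    ``weights`` maps group label -> contrast weight (must sum to 0).  For a
    one-tailed test, ``direction`` names the hypothesized larger group (one
    of the two non-zero-weight groups); an observed effect opposite to the
    hypothesis yields p > 0.5.  Cohen's d divides the difference of the two
    contrasted group means by the root pooled MSE.
    """
    anova = oneway_anova(values, groups)
    labels = list(anova.group_means)
    w = np.array([weights.get(g, 0.0) for g in labels], dtype=float)
    if abs(w.sum()) > 1e-12:
        raise SrmptError(f"contrast weights sum to {w.sum():g}, not 0")
    means = np.array([anova.group_means[g] for g in labels])
    ns = np.array([anova.group_ns[g] for g in labels], dtype=float)
    estimate = float(w @ means)
    se = math.sqrt(anova.ms_error * float(np.sum(w**2 / ns)))
    t = estimate / se
    df = anova.df2
    if tail == "two":
        p = float(2 * stats.t.sf(abs(t), df))
    elif tail == "one":
        if direction is None:
            raise SrmptError("one-tailed contrast requires the hypothesized larger group")
        sign = 1.0 if weights.get(direction, 0.0) > 0 else -1.0
        p = float(stats.t.sf(sign * t, df))
    else:
        raise SrmptError(f"unknown tail {tail!r}")
    nonzero = [g for g in labels if weights.get(g, 0.0) != 0]
    d = None
    if len(nonzero) == 2:
        a, b = nonzero
        if weights[a] < weights[b]:
            a, b = b, a
        d = float((anova.group_means[a] - anova.group_means[b]) / math.sqrt(anova.ms_error))
    return ContrastResult(dict(weights), estimate, float(t), df, p, tail, d)


# ---------------------------------------------------------------------------
# design / power
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignSpec:
    """A-priori design parameters for the three-group ANOVA."""

    k: int = 3
    f: float = 0.25
    alpha: float = 0.05
    power: float = 0.80
    oversampling: float = 0.0
    n_targets: int = 20
    n_distractors: int = 20
    learning_criterion: int = 7
    max_cycles: int = 3

    def __post_init__(self):
        if self.k < 2:
            raise DomainError("k must be >= 2")
        if self.f <= 0:
            raise DomainError("effect size f must be > 0")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise DomainError("alpha and power must lie in (0, 1)")


def anova_power(n_total: int, k: int, f: float, alpha: float) -> float:
    """Power of the one-way ANOVA F test via the noncentral F distribution.

    Noncentrality lambda = f^2 * N with df1 = k-1, df2 = N-k.
    """
    df1, df2 = k - 1, n_total - k
    if df2 <= 0:
        return 0.0
    crit = stats.f.isf(alpha, df1, df2)
    return float(stats.ncf.sf(crit, df1, df2, f**2 * n_total))


def required_sample_size(design: DesignSpec) -> tuple[int, int]:
    """Smallest total N divisible by k reaching the target power.

    Returns ``(N_total, n_per_group)``.
    """
    k = design.k
    n_total = 2 * k
    while anova_power(n_total, k, design.f, design.alpha) < design.power:
        n_total += k
        if n_total > 10_000_000:
            raise DomainError("power target unreachable")
    return n_total, n_total // k


def oversampled_n(per_group_n: int, fraction: float, k: int = 3) -> tuple[int, int]:
    """Inflate the per-group n by ``fraction`` (ceiling) and total over k groups."""
    if fraction < 0:
        raise DomainError("oversampling fraction must be >= 0")
    n = math.ceil(per_group_n * (1.0 + fraction))
    return n * k, n
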