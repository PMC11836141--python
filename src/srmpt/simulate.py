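"""Synthetic recognition + cued-recall experiments.

Generates complete three-condition datasets with the statistical structure
the downstream analyses assume: per-participant parameter heterogeneity on
the probit scale, a 20-target/20-distractor delayed test, and an immediate
cued-recall learning criterion (7/20) with up to three study-test cycles.

All randomness flows from one explicit seed; identical seeds give identical
tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .errors import DomainError
from .model import (
    DEFAULT_CONDITIONS,
    CategoryCounts,
    ModelSpec,
    category_probabilities,
    storage_retrieval_model,
)

__all__ = [
    "ExperimentDesign",
    "TrueParameters",
    "CATEGORY_COLUMNS",
    "PARTICIPANT_COLUMNS",
    "draw_participant_parameters",
    "simulate_counts",
    "simulate_experiment",
    "expected_frequencies",
    "write_simulation",
    "aggregate_counts",
    "participant_count_matrix",
]

#: CSV-safe column names for the six canonical response categories
CATEGORY_COLUMNS = {
    "Rn+Rc+": "RnpRcp",
    "Rn+Rc-": "RnpRcm",
    "Rn-Rc+": "RnmRcp",
    "Rn-Rc-": "RnmRcm",
    "D+": "Dp",
    "D-": "Dm",
}

PARTICIPANT_COLUMNS = [
    "id",
    "condition",
    "session",
    "cycles",
    "immediate_correct",
    "RnpRcp",
    "RnpRcm",
    "RnmRcp",
    "RnmRcm",
    "Dp",
    "Dm",
    "excluded",
]


@dataclass(frozen=True)
class ExperimentDesign:
    """Fixed structural constants of the experiment."""

    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_per_condition: int = 53
    n_targets: int = 20
    n_distractors: int = 20
    n_buffer: int = 4  # presented but never tested
    learning_criterion: int = 7  # 35% of 20
    max_cycles: int = 3
    sessions: int = 1

    def __post_init__(self):
        if self.n_per_condition <= 0 or self.n_targets <= 0 or self.n_distractors <= 0:
            raise DomainError("counts must be positive")
        if self.sessions not in (1, 2):
            raise DomainError("sessions must be 1 or 2")


_PARAMS = ("s", "r1", "g", "r2")

#: group-level probabilities close to the aggregated Session-1 estimates
_DEFAULT_MEANS = {
    "waking_rest": {"s": 0.91, "r1": 0.98, "g": 0.46, "r2": 0.73},
    "social_media": {"s": 0.92, "r1": 0.98, "g": 0.38, "r2": 0.73},
    "vocabulary": {"s": 0.87, "r1": 0.96, "g": 0.27, "r2": 0.68},
}


def _default_means() -> dict:
    return {k: dict(v) for k, v in _DEFAULT_MEANS.items()}


@dataclass
class TrueParameters:
    """Generating parameters: group probabilities + heterogeneity.

    ``means`` maps condition -> {parameter -> probability}; individual
    parameters are theta_ik = Phi(probit(mean_k) + delta_ik) with
    delta_i ~ N(0, Sigma).  ``encoding_mean`` governs immediate-recall
    performance (a simulator-only construct, not an MPT parameter) and
    ``cycle_increment`` is the probit-scale gain per repeated study-test
    cycle.
    """

    means: dict = field(default_factory=_default_means)
    sigma: np.ndarray | float = 0.3
    encoding_mean: float = 0.58
    encoding_sd: float = 0.45
    cycle_increment: float = 0.35

    def covariance(self, k: int = len(_PARAMS)) -> np.ndarray:
        sig = self.sigma
        if np.isscalar(sig):
            cov = float(sig) ** 2 * np.eye(k)
        else:
            cov = np.asarray(sig, dtype=float)
            if cov.shape != (k, k):
                raise DomainError(f"sigma must be scalar or ({k}, {k})")
        eig = np.linalg.eigvalsh(cov)
        if np.any(eig < -1e-10):
            raise DomainError("sigma is not positive semi-definite")
        return cov

    def __post_init__(self):
        for cond, vals in self.means.items():
            for p in _PARAMS:
                if not 0 < vals.get(p, -1) < 1:
                    raise DomainError(f"mean for {p!r} in {cond!r} must be in (0, 1)")


def draw_participant_parameters(
    true: TrueParameters,
    condition: str,
    n: int,
    rng: np.random.Generator | int | None,
) -> np.ndarray:
    """Draw an (n, 4) array of per-participant (s, r1, g, r2)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    mu = ndtri([true.means[condition][p] for p in _PARAMS])
    cov = true.covariance()
    delta = rng.multivariate_normal(np.zeros(len(_PARAMS)), cov, size=n, method="cholesky") \
        if np.any(cov) else np.zeros((n, len(_PARAMS)))
    # ndtr saturates to exactly 0/1 in float for |x| > ~8; keep theta interior
    return np.clip(ndtr(mu + delta), 1e-12, 1.0 - 1e-12)


def simulate_counts(
    theta: np.ndarray,
    design: ExperimentDesign,
    rng: np.random.Generator | int | None,
    spec: ModelSpec | None = None,
) -> np.ndarray:
    """Delayed-test category counts for each row of ``theta``.

    Returns an (n, 6) integer array in the canonical category order
    (4 target categories summing to ``n_targets``, then D+, D- summing to
    ``n_distractors``).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    spec = spec or storage_retrieval_model()
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    if np.any(theta < 0) or np.any(theta > 1):
        raise DomainError("theta entries must lie in [0, 1]")
    params = dict(zip(_PARAMS, theta.T))
    probs = category_probabilities(spec, params)
    n = theta.shape[0]
    out = np.empty((n, 6), dtype=int)
    p_target = np.column_stack([probs["target"][c] * np.ones(n) for c in spec.tree("target").categories])
    p_dist = np.column_stack([probs["distractor"][c] * np.ones(n) for c in spec.tree("distractor").categories])
    for i in range(n):
        out[i, :4] = rng.multinomial(design.n_targets, p_target[i] / p_target[i].sum())
        out[i, 4:] = rng.multinomial(design.n_distractors, p_dist[i] / p_dist[i].sum())
    return out


def simulate_experiment(
    design: ExperimentDesign | None = None,
    true: TrueParameters | None = None,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Simulate a full experiment as a tidy participant table.

    Per participant: an encoding probability e_i is drawn probit-normally;
    immediate-recall cycles are Binomial(n_targets, e) with a fixed probit
    increment per repetition; participants below the learning criterion on
    every cycle are flagged ``excluded``.  Delayed category counts come from
    the storage-retrieval model at the participant's theta_i (independently
    of immediate recall, so retention scores may exceed 1).  With
    ``design.sessions == 2`` each participant gets a second delayed test row
    with a fresh distractor set.
    """
    design = design or ExperimentDesign()
    true = true or TrueParameters()
    rng = np.random.default_rng(seed)
    spec = storage_retrieval_model()
    rows = []
    pid = 0
    mu_e = ndtri(true.encoding_mean)
    for condition in design.conditions:
        theta = draw_participant_parameters(true, condition, design.n_per_condition, rng)
        counts_s1 = simulate_counts(theta, design, rng, spec)
        counts_s2 = (
            simulate_counts(theta, design, rng, spec) if design.sessions == 2 else None
        )
        e_probit = mu_e + true.encoding_sd * rng.standard_normal(design.n_per_condition)
        for i in range(design.n_per_condition):
            pid += 1
            cycles, immediate, reached = design.max_cycles, 0, False
            for c in range(design.max_cycles):
                p_enc = ndtr(e_probit[i] + c * true.cycle_increment)
                immediate = int(rng.binomial(design.n_targets, p_enc))
                if immediate >= design.learning_criterion:
                    cycles, reached = c + 1, True
                    break
            for session, cts in ((1, counts_s1), (2, counts_s2)):
                if cts is None:
                    continue
                rows.append(
                    [pid, condition, session, cycles, immediate, *cts[i], not reached]
                )
    return pd.DataFrame(rows, columns=PARTICIPANT_COLUMNS)


def expected_frequencies(
    spec: ModelSpec,
    params: Mapping[str, float],
    totals: Mapping[str, float],
    rounded: bool = False,
) -> CategoryCounts:
    """Deterministic expected counts: totals x category probabilities.

    With ``rounded`` the real-valued expectations are converted to integers
    by largest-remainder rounding, preserving each tree's total exactly.
    """
    probs = category_probabilities(spec, params)
    counts: dict[str, dict[str, float]] = {}
    for tree in spec.trees:
        total = float(totals[tree.name])
        if total <= 0:
            raise DomainError(f"total for tree {tree.name!r} must be > 0")
        raw = {c: total * probs[tree.name][c] for c in tree.categories}
        if rounded:
            floors = {c: math.floor(v) for c, v in raw.items()}
            short = round(total) - sum(floors.values())
            order = sorted(raw, key=lambda c: raw[c] - floors[c], reverse=True)
            for c in order[: int(short)]:
                floors[c] += 1
            raw = {c: float(floors[c]) for c in raw}
        counts[tree.name] = raw
    return CategoryCounts(counts)


def write_simulation(
    records: pd.DataFrame,
    path,
    design: ExperimentDesign,
    true: TrueParameters,
    seed: int | None,
) -> None:
    """Write the participant CSV plus a sidecar JSON with the ground truth."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    path = Path(path)
    records.to_csv(path, index=False)
    sigma = true.sigma
    sidecar = {
        "schema_version": 1,
        "seed": seed,
        "design": asdict(design),
        "true_parameters": {
            "means": true.means,
            "sigma": sigma.tolist() if isinstance(sigma, np.ndarray) else sigma,
            "encoding_mean": true.encoding_mean,
            "encoding_sd": true.encoding_sd,
            "cycle_increment": true.cycle_increment,
        },
    }
    with open(path.with_suffix(".json"), "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")


def aggregate_counts(
    records: pd.DataFrame, spec: ModelSpec | None = None, session: int | None = None
) -> dict[str, CategoryCounts]:
    """Sum per-participant category counts into per-condition CategoryCounts.

    Excluded participants (criterion failures) are dropped.
    """
    spec = spec or storage_retrieval_model()
    df = records
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    if session is not None and "session" in df.columns:
        df = df[df["session"] == session]
    out: dict[str, CategoryCounts] = {}
    for condition, sub in df.groupby("condition", sort=False):
        vec = [sub[CATEGORY_COLUMNS[c]].sum() for c in _canonical_labels(spec)]
        out[str(condition)] = CategoryCounts.from_vector(spec, vec)
    return out


def participant_count_matrix(
    records: pd.DataFrame, condition: str, session: int = 1
) -> np.ndarray:
    """(n, 6) per-participant count matrix for one condition/session."""
    df = records
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    df = df[(df["condition"] == condition)]
    if "session" in df.columns:
        df = df[df["session"] == session]
    cols = [CATEGORY_COLUMNS[c] for c in _canonical_labels(storage_retrieval_model())]
    return df[cols].to_numpy(dtype=float)


def _canonical_labels(spec: ModelSpec) -> list[str]:
    out = []
    for tree in spec.trees:
        out.extend(tree.categories)
    return out
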