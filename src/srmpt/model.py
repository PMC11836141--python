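"""Binary multinomial-processing-tree (MPT) models.

A model is a collection of named trees; every branch of a tree is a product
of parameter terms (a parameter ``p`` or its complement ``(1-p)``) ending in
an observable response category.  The module provides

* an EQN-format reader/writer (the de-facto MPT interchange format),
* exact category probabilities by branch-product enumeration,
* constraint handling (product substitutions such as ``d := s*r1``,
  fixed values, and equality constraints within or across groups),
* degrees-of-freedom accounting and a numerical local-identifiability check,
* a symbolic (sympy) compilation of the constrained multi-group model used
  by the maximum-likelihood machinery for analytic gradients.

The built-in storage-retrieval model for recognition + cued-recall data
(parameters ``s``, ``r1``, ``g``, ``r2`` and distractor detection
``d = s*r1``) ships as a packaged EQN fixture, see
:func:`storage_retrieval_model`.
"""

from __future__ import annotations

import functools
import importlib.resources
import io
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import sympy as sp

from .errors import (
    ConstraintError,
    DomainError,
    EqnParseError,
    StructuralError,
)

__all__ = [
    "Term",
    "Branch",
    "Tree",
    "Substitution",
    "Fix",
    "Equal",
    "ModelSpec",
    "CategoryCounts",
    "DfAccount",
    "ConstrainedModel",
    "parse_eqn",
    "write_eqn",
    "read_eqn_file",
    "storage_retrieval_model",
    "category_probabilities",
    "apply_constraints",
    "check_identifiability",
    "df_account",
    "build_constrained",
]

#: canonical condition names of the three-group design
DEFAULT_CONDITIONS = ("waking_rest", "social_media", "vocabulary")

#: canonical category labels of the built-in model
TARGET_CATEGORIES = ("Rn+Rc+", "Rn+Rc-", "Rn-Rc+", "Rn-Rc-")
DISTRACTOR_CATEGORIES = ("D+", "D-")


# ---------------------------------------------------------------------------
# core structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Term:
    """One factor of a branch product: a parameter or its complement."""

    parameter: str
    complement: bool = False

    def __str__(self) -> str:
        return f"(1-{self.parameter})" if self.complement else self.parameter


@dataclass(frozen=True)
class Branch:
    """A path through a tree ending in ``category``."""

    category: str
    terms: tuple[Term, ...]

    def probability(self, values: Mapping[str, float]):
        out = 1.0
        for t in self.terms:
            v = values[t.parameter]
            out = out * ((1.0 - v) if t.complement else v)
        return out

    def __str__(self) -> str:
        return "*".join(str(t) for t in self.terms) if self.terms else "1"


@dataclass(frozen=True)
class Tree:
    """A named tree: an ordered list of branches."""

    name: str
    branches: tuple[Branch, ...]

    @property
    def categories(self) -> tuple[str, ...]:
        seen: list[str] = []
        for b in self.branches:
            if b.category not in seen:
                seen.append(b.category)
        return tuple(seen)


# -- constraints ------------------------------------------------------------

ParamRef = tuple[str, str | None]  # (parameter, group); group None = any/all


@dataclass(frozen=True)
class Substitution:
    """Product substitution, e.g. ``d := s*r1``."""

    parameter: str
    factors: tuple[str, ...]

    def __str__(self) -> str:
        return f"{self.parameter}:={'*'.join(self.factors)}"


@dataclass(frozen=True)
class Fix:
    """Fix a parameter (optionally in a single group) to a constant."""

    parameter: str
    value: float
    group: str | None = None

    def __str__(self) -> str:
        lhs = self.parameter if self.group is None else f"{self.parameter}[{self.group}]"
        return f"{lhs}={self.value:g}"


@dataclass(frozen=True)
class Equal:
    """Equality constraint between parameter instances.

    A member with ``group=None`` expands to that parameter in *every* group,
    so ``Equal((("g", None),))`` means "g equal across all groups".
    """

    members: tuple[ParamRef, ...]

    def __str__(self) -> str:
        def fmt(m: ParamRef) -> str:
            return m[0] if m[1] is None else f"{m[0]}[{m[1]}]"

        return "=".join(fmt(m) for m in self.members)


Constraint = Substitution | Fix | Equal

_CONSTRAINT_REF_RE = re.compile(r"^([A-Za-z_]\w*)(?:\[([^\]]+)\])?$")


def parse_constraint(text: str) -> Constraint:
    """Parse a constraint from its string form.

    Supported forms: ``d:=s*r1`` (substitution), ``g=0.5`` / ``g[vocabulary]=0.5``
    (fixation), ``r1[waking_rest]=r1[social_media]`` or ``g=g`` -- equivalently
    just ``g`` with an ``=`` chain -- (equalities; a bare reference without a
    group applies across all groups).
    """
    text = text.strip()
    if ":=" in text:
        lhs, rhs = text.split(":=", 1)
        factors = tuple(f.strip() for f in rhs.split("*"))
        if not lhs.strip() or not all(factors):
            raise ConstraintError(f"bad substitution: {text!r}")
        return Substitution(lhs.strip(), factors)
    parts = [p.strip() for p in text.split("=")]
    if len(parts) == 2:
        try:
            value = float(parts[1])
        except ValueError:
            pass
        else:
            m = _CONSTRAINT_REF_RE.match(parts[0])
            if not m:
                raise ConstraintError(f"bad fixation lhs: {parts[0]!r}")
            return Fix(m.group(1), value, m.group(2))
    members = []
    for p in parts:
        m = _CONSTRAINT_REF_RE.match(p)
        if not m:
            raise ConstraintError(f"bad parameter reference: {p!r}")
        members.append((m.group(1), m.group(2)))
    if len(members) < 2:
        raise ConstraintError(f"equality needs at least two members: {text!r}")
    return Equal(tuple(members))


@dataclass(frozen=True)
class ModelSpec:
    """A validated MPT model plus its constraint set."""

    trees: tuple[Tree, ...]
    parameters: tuple[str, ...]
    constraints: tuple[Constraint, ...] = ()

    def __post_init__(self):
        declared = set(self.parameters)
        for tree in self.trees:
            for b in tree.branches:
                for t in b.terms:
                    if t.parameter not in declared:
                        raise StructuralError(
                            f"branch term references undeclared parameter {t.parameter!r}"
                        )
        labels_elsewhere: set[str] = set()
        for tree in self.trees:
            cats = set(tree.categories)
            if cats & labels_elsewhere:
                raise StructuralError(
                    f"category labels {cats & labels_elsewhere} appear in multiple trees"
                )
            labels_elsewhere |= cats
        _check_completeness(self)
        _validate_constraints(self)

    @property
    def tree_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.trees)

    def tree(self, name: str) -> Tree:
        for t in self.trees:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def substituted(self) -> dict[str, tuple[str, ...]]:
        return {c.parameter: c.factors for c in self.constraints if isinstance(c, Substitution)}

    @property
    def base_parameters(self) -> tuple[str, ...]:
        """Parameters that remain after product substitutions."""
        subs = self.substituted
        return tuple(p for p in self.parameters if p not in subs)

    def with_constraints(self, extra: Iterable[Constraint | str]) -> "ModelSpec":
        parsed = tuple(
            parse_constraint(c) if isinstance(c, str) else c for c in extra
        )
        merged = list(self.constraints)
        for c in parsed:
            if c not in merged:
                merged.append(c)
        return replace(self, constraints=tuple(merged))

    def category_labels(self) -> tuple[str, ...]:
        out: list[str] = []
        for tree in self.trees:
            out.extend(tree.categories)
        return tuple(out)


def _check_completeness(spec: ModelSpec, n_probe: int = 25, tol: float = 1e-10) -> None:
    rng = np.random.default_rng(0)
    probes = list(rng.uniform(0.05, 0.95, size=(n_probe, len(spec.parameters))))
    probes.append(np.full(len(spec.parameters), 0.5))
    for vec in probes:
        values = dict(zip(spec.parameters, vec))
        for tree in spec.trees:
            total = sum(b.probability(values) for b in tree.branches)
            if abs(total - 1.0) > tol:
                raise StructuralError(
                    f"tree {tree.name!r}: branch probabilities sum to {total:.12g}, not 1"
                )


def _expand_substitution(
    subs: Mapping[str, tuple[str, ...]], parameter: str, _stack: tuple[str, ...] = ()
) -> tuple[str, ...]:
    """Expand a substituted parameter into base-parameter factors; reject cycles."""
    if parameter in _stack:
        raise ConstraintError(f"cyclic substitution involving {parameter!r}")
    if parameter not in subs:
        return (parameter,)
    out: list[str] = []
    for f in subs[parameter]:
        out.extend(_expand_substitution(subs, f, _stack + (parameter,)))
    return tuple(out)


def _validate_constraints(spec: ModelSpec) -> None:
    declared = set(spec.parameters)
    for c in spec.constraints:
        if isinstance(c, Substitution):
            if c.parameter not in declared:
                raise ConstraintError(f"substitution of undeclared parameter {c.parameter!r}")
            for f in c.factors:
                if f not in declared:
                    raise ConstraintError(f"substitution factor {f!r} undeclared")
        elif isinstance(c, Fix):
            if c.parameter not in declared:
                raise ConstraintError(f"fixation of undeclared parameter {c.parameter!r}")
            if not 0.0 <= c.value <= 1.0:
                raise ConstraintError(f"fixed value {c.value} outside [0, 1]")
        elif isinstance(c, Equal):
            for p, _ in c.members:
                if p not in declared:
                    raise ConstraintError(f"equality references undeclared parameter {p!r}")
    subs = spec.substituted
    for p in subs:
        _expand_substitution(subs, p)  # raises on cycles


# ---------------------------------------------------------------------------
# EQN parsing / writing
# ---------------------------------------------------------------------------

_FACTOR_RE = re.compile(r"^(?:([A-Za-z_]\w*)|\(\s*1\s*-\s*([A-Za-z_]\w*)\s*\))$")


def _parse_expression(expr: str, line_number: int) -> tuple[Term, ...]:
    terms = []
    for factor in expr.split("*"):
        factor = factor.strip()
        m = _FACTOR_RE.match(factor)
        if not m:
            raise EqnParseError(f"cannot parse factor {factor!r}", line_number)
        if m.group(1):
            terms.append(Term(m.group(1)))
        else:
            terms.append(Term(m.group(2), complement=True))
    return tuple(terms)


def parse_eqn(text: str, constraints: Iterable[Constraint | str] = ()) -> ModelSpec:
    """Parse an EQN-format model description.

    One branch per line: ``tree-id  category  product-expression`` with ``#``
    comments.  Products are over parameter names and complements ``(1-p)``;
    no other arithmetic is allowed.  A first non-comment line consisting of a
    single integer (branch-count header, MultiTree convention) is skipped.
    """
    branches_per_tree: dict[str, list[Branch]] = {}
    parameters: list[str] = []
    first_content = True
    for line_number, raw in enumerate(io.StringIO(text), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if first_content:
            first_content = False
            if re.fullmatch(r"[+-]?\d+", line):
                continue  # header line
        fields = line.split(None, 2)
        if len(fields) != 3:
            raise EqnParseError(
                f"expected 'tree category expression', got {line!r}", line_number
            )
        tree_id, category, expr = fields
        terms = _parse_expression(expr, line_number)
        for t in terms:
            if t.parameter not in parameters:
                parameters.append(t.parameter)
        branches_per_tree.setdefault(tree_id, []).append(Branch(category, terms))
    if not branches_per_tree:
        raise EqnParseError("no branches found")
    trees = tuple(
        Tree(name, tuple(branches)) for name, branches in branches_per_tree.items()
    )
    spec = ModelSpec(trees, tuple(parameters))
    if constraints:
        spec = spec.with_constraints(constraints)
    return spec


def write_eqn(spec: ModelSpec, header: bool = True) -> str:
    """Serialize a model back to EQN text (constraints are not representable)."""
    lines = []
    n = sum(len(t.branches) for t in spec.trees)
    if header:
        lines.append(str(n))
    for tree in spec.trees:
        for b in tree.branches:
            lines.append(f"{tree.name} {b.category} {b}")
    return "\n".join(lines) + "\n"


def read_eqn_file(path, constraints: Iterable[Constraint | str] = ()) -> ModelSpec:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_eqn(fh.read(), constraints)


def storage_retrieval_model(with_substitution: bool = True) -> ModelSpec:
    """The built-in storage-retrieval model for recognition + cued recall.

    Parameters: storage ``s``, recognition retrieval ``r1``, guessing "old"
    ``g``, cued-recall retrieval ``r2`` and distractor detection ``d``.  With
    ``with_substitution`` (default) the identifying product substitution
    ``d := s*r1`` is attached, leaving four base parameters.
    """
    text = (
        importlib.resources.files("srmpt.data")
        .joinpath("storage_retrieval.eqn")
        .read_text(encoding="utf-8")
    )
    constraints = ("d:=s*r1",) if with_substitution else ()
    return parse_eqn(text, constraints)


# ---------------------------------------------------------------------------
# category counts
# ---------------------------------------------------------------------------

class CategoryCounts:
    """Per-tree, per-category frequencies (observed or expected).

    ``counts`` maps tree name -> {category label -> nonnegative count}.
    Real-valued entries are allowed (expected frequencies); observed data are
    integer-valued by convention but not enforced.
    """

    def __init__(self, counts: Mapping[str, Mapping[str, float]]):
        self.counts: dict[str, dict[str, float]] = {
            tree: dict(cats) for tree, cats in counts.items()
        }
        for tree, cats in self.counts.items():
            for cat, value in cats.items():
                if value < 0:
                    raise DomainError(f"negative count for {tree}/{cat}: {value}")

    @property
    def totals(self) -> dict[str, float]:
        return {tree: float(sum(cats.values())) for tree, cats in self.counts.items()}

    def vector(self, spec: ModelSpec) -> np.ndarray:
        """Counts flattened in the spec's canonical category order."""
        out = []
        for tree in spec.trees:
            cats = self.counts.get(tree.name, {})
            out.extend(float(cats.get(c, 0.0)) for c in tree.categories)
        return np.asarray(out)

    @classmethod
    def from_vector(cls, spec: ModelSpec, vec: Sequence[float]) -> "CategoryCounts":
        vec = list(vec)
        counts: dict[str, dict[str, float]] = {}
        i = 0
        for tree in spec.trees:
            counts[tree.name] = {}
            for c in tree.categories:
                counts[tree.name][c] = float(vec[i])
                i += 1
        if i != len(vec):
            raise DomainError(f"expected {i} counts, got {len(vec)}")
        return cls(counts)

    def __eq__(self, other) -> bool:
        return isinstance(other, CategoryCounts) and self.counts == other.counts

    def __repr__(self) -> str:
        return f"CategoryCounts({self.counts!r})"


# ---------------------------------------------------------------------------
# probabilities, constraints, df
# ---------------------------------------------------------------------------

def _resolved_values(spec: ModelSpec, params: Mapping[str, float]) -> dict:
    """Full parameter values with substitutions expanded; validates domain."""
    subs = spec.substituted
    values = {}
    for p in spec.parameters:
        if p in subs:
            continue
        if p not in params:
            raise DomainError(f"missing value for parameter {p!r}")
        v = params[p]
        arr = np.asarray(v, dtype=float)
        if np.any(arr < 0) or np.any(arr > 1):
            raise DomainError(f"parameter {p!r} outside [0, 1]")
        values[p] = v
    for p in subs:
        factors = _expand_substitution(subs, p)
        out = 1.0
        for f in factors:
            out = out * values[f]
        values[p] = out
    return values


def category_probabilities(
    spec: ModelSpec, params: Mapping[str, float]
) -> dict[str, dict[str, float]]:
    """Exact category probabilities by summing branch products.

    Values in ``params`` may be scalars or numpy arrays (broadcast).  Any
    product substitution in the spec (``d := s*r1``) is applied automatically;
    substituted parameters need not (but may not conflictingly) be supplied.
    """
    values = _resolved_values(spec, params)
    out: dict[str, dict[str, float]] = {}
    for tree in spec.trees:
        probs: dict[str, float] = {c: 0.0 for c in tree.categories}
        for b in tree.branches:
            probs[b.category] = probs[b.category] + b.probability(values)
        out[tree.name] = probs
    return out


def apply_constraints(
    spec: ModelSpec, constraints: Iterable[Constraint | str]
) -> ModelSpec:
    """Return a spec with additional constraints attached (idempotent)."""
    return spec.with_constraints(constraints)


@dataclass(frozen=True)
class DfAccount:
    """Degrees-of-freedom bookkeeping for a (multi-group) fit."""

    free_categories: int
    free_parameters: int

    @property
    def df(self) -> int:
        return self.free_categories - self.free_parameters


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic representative: lexicographically smallest
            lo, hi = sorted([ra, rb], key=lambda r: (str(r[0]), str(r[1])))
            self.parent[hi] = lo


class ConstrainedModel:
    """A multi-group model compiled to numeric + symbolic form.

    Resolution order: product substitutions first, then fixations, then
    equalities.  Free parameters are equality-class representatives that are
    not fixed; each maps to one sympy symbol.  ``prob_fn(theta)`` returns the
    flat vector of category probabilities over (group, tree, category) in
    canonical order, ``jac_fn(theta)`` its analytic Jacobian.
    """

    def __init__(self, spec: ModelSpec, groups: Sequence[str | None] | None = None):
        self.spec = spec
        self.groups: tuple = tuple(groups) if groups is not None else (None,)
        if len(set(self.groups)) != len(self.groups):
            raise ConstraintError("duplicate group names")
        subs = spec.substituted

        uf = _UnionFind()
        base = spec.base_parameters
        for p in base:
            for grp in self.groups:
                uf.find((p, grp))
        for c in spec.constraints:
            if isinstance(c, Equal):
                refs: list[tuple[str, str | None]] = []
                for p, grp in c.members:
                    if p in subs:
                        raise ConstraintError(
                            f"cannot equate substituted parameter {p!r}"
                        )
                    if grp is None:
                        refs.extend((p, g) for g in self.groups)
                    else:
                        if grp not in self.groups:
                            raise ConstraintError(f"unknown group {grp!r} in {c}")
                        refs.append((p, grp))
                for other in refs[1:]:
                    uf.union(refs[0], other)

        fixed: dict[tuple, float] = {}
        for c in spec.constraints:
            if isinstance(c, Fix):
                if c.parameter in subs:
                    raise ConstraintError(
                        f"cannot fix substituted parameter {c.parameter!r}"
                    )
                targets = (
                    [(c.parameter, g) for g in self.groups]
                    if c.group is None
                    else [(c.parameter, c.group)]
                )
                for t in targets:
                    rep = uf.find(t)
                    if rep in fixed and fixed[rep] != c.value:
                        raise ConstraintError(
                            f"parameter {t[0]!r} fixed to both {fixed[rep]} and {c.value}"
                        )
                    fixed[rep] = c.value

        reps: list[tuple] = []
        for p in base:
            for grp in self.groups:
                rep = uf.find((p, grp))
                if rep not in fixed and rep not in reps:
                    reps.append(rep)
        self._uf = uf
        self._fixed = fixed
        self.free_names: tuple[tuple, ...] = tuple(reps)

        def sym_name(rep) -> str:
            p, grp = rep
            return p if grp is None else f"{p}__{grp}"

        self._symbols = [sp.Symbol(sym_name(r), positive=True) for r in reps]
        sym_of = dict(zip(reps, self._symbols))

        def base_expr(p: str, grp) -> sp.Expr:
            rep = uf.find((p, grp))
            if rep in fixed:
                return sp.Float(fixed[rep])
            return sym_of[rep]

        def param_expr(p: str, grp) -> sp.Expr:
            factors = _expand_substitution(subs, p)
            out: sp.Expr = sp.Integer(1)
            for f in factors:
                out = out * base_expr(f, grp)
            return out

        exprs: list[sp.Expr] = []
        self.layout: list[tuple] = []  # (group, tree, category) per output slot
        for grp in self.groups:
            for tree in spec.trees:
                cat_exprs = {c: sp.Integer(0) for c in tree.categories}
                for b in tree.branches:
                    prod: sp.Expr = sp.Integer(1)
                    for t in b.terms:
                        e = param_expr(t.parameter, grp)
                        prod = prod * ((1 - e) if t.complement else e)
                    cat_exprs[b.category] = cat_exprs[b.category] + prod
                for c in tree.categories:
                    exprs.append(sp.expand(cat_exprs[c]))
                    self.layout.append((grp, tree.name, c))

        mat = sp.Matrix(exprs)
        jac = mat.jacobian(self._symbols) if self._symbols else sp.zeros(len(exprs), 0)
        args = list(self._symbols)
        self._prob_fn = sp.lambdify(args, mat, modules="numpy")
        self._jac_fn = sp.lambdify(args, jac, modules="numpy")
        self._n_out = len(exprs)

    # -- public surface ----------------------------------------------------
    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def df_account(self) -> DfAccount:
        free_cats = len(self.groups) * sum(
            len(t.categories) - 1 for t in self.spec.trees
        )
        return DfAccount(free_cats, self.n_free)

    def prob_vector(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_free,):
            raise DomainError(f"theta must have shape ({self.n_free},)")
        out = np.asarray(self._prob_fn(*theta), dtype=float).reshape(self._n_out)
        return out

    def jacobian(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        out = np.asarray(self._jac_fn(*theta), dtype=float)
        return out.reshape(self._n_out, self.n_free)

    def parameter_values(self, theta: np.ndarray) -> dict:
        """Full per-group parameter dictionaries implied by ``theta``."""
        theta = np.asarray(theta, dtype=float)
        lookup = dict(zip(self.free_names, theta))
        subs = self.spec.substituted
        out: dict = {}
        for grp in self.groups:
            values = {}
            for p in self.spec.base_parameters:
                rep = self._uf.find((p, grp))
                values[p] = self._fixed[rep] if rep in self._fixed else float(lookup[rep])
            for p in subs:
                prod = 1.0
                for f in _expand_substitution(subs, p):
                    prod *= values[f]
                values[p] = prod
            out[grp] = values
        return out

    def theta_from_parameters(self, per_group: Mapping) -> np.ndarray:
        """Inverse of :meth:`parameter_values` for free entries (best effort)."""
        theta = np.empty(self.n_free)
        for i, (p, grp) in enumerate(self.free_names):
            theta[i] = per_group[grp][p]
        return theta

    def counts_vector(self, counts_by_group: Mapping) -> np.ndarray:
        """Flatten per-group CategoryCounts in this model's output order."""
        out = []
        for grp in self.groups:
            counts = counts_by_group[grp]
            out.append(counts.vector(self.spec))
        return np.concatenate(out)


@functools.lru_cache(maxsize=128)
def _cached_constrained(spec: ModelSpec, groups: tuple | None) -> ConstrainedModel:
    return ConstrainedModel(spec, groups)


def build_constrained(
    spec: ModelSpec,
    groups: Sequence[str | None] | None = None,
    constraints: Iterable[Constraint | str] = (),
) -> ConstrainedModel:
    """Compile a constrained multi-group model (memoized; models are stateless)."""
    if constraints:
        spec = spec.with_constraints(constraints)
    return _cached_constrained(spec, tuple(groups) if groups is not None else None)


def df_account(
    spec: ModelSpec,
    groups: Sequence[str | None] | None = None,
    constraints: Iterable[Constraint | str] = (),
) -> DfAccount:
    """Degrees of freedom of a (multi-group) model after constraints."""
    return build_constrained(spec, groups, constraints).df_account()


# ---------------------------------------------------------------------------
# identifiability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IdentifiabilityReport:
    n_free_parameters: int
    n_free_categories: int
    ranks: tuple[int, ...]

    @property
    def min_rank(self) -> int:
        return min(self.ranks)

    @property
    def max_rank(self) -> int:
        return max(self.ranks)

    @property
    def locally_identifiable(self) -> bool:
        return all(r == self.n_free_parameters for r in self.ranks)


def check_identifiability(
    spec: ModelSpec,
    n_probe: int = 20,
    seed: int | None = 0,
    groups: Sequence[str | None] | None = None,
) -> IdentifiabilityReport:
    """Numerical local-identifiability check.

    Evaluates the Jacobian of the *free* category probabilities (one category
    dropped per tree, since they sum to 1) with respect to the free parameters
    at ``n_probe`` random interior points and reports the observed ranks.
    """
    if n_probe < 1:
        raise DomainError("n_probe must be >= 1")
    model = build_constrained(spec, groups)
    # drop the last category of each (group, tree) block
    keep = []
    for i, (grp, tree_name, cat) in enumerate(model.layout):
        tree = model.spec.tree(tree_name)
        if cat != tree.categories[-1]:
            keep.append(i)
    keep = np.asarray(keep, dtype=int)
    rng = np.random.default_rng(seed)
    ranks = []
    for _ in range(n_probe):
        theta = rng.uniform(0.15, 0.85, size=model.n_free)
        J = model.jacobian(theta)[keep, :]
        ranks.append(int(np.linalg.matrix_rank(J, tol=1e-9)))
    return IdentifiabilityReport(model.n_free, len(keep), tuple(ranks))
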