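"""Construction and evaluation of causally informative entropic inequalities.

Every inequality here has the shape

    upper_bound  >=  sum of lower-bound terms,

where the upper bound follows from an instrumental-style independence
(Z ⊥ U | B0 gives H(X|B0); group independence gives H(Y|Z); X ⊥ U gives the
Information Causality bound) and each lower-bound term is licensed by a data
processing inequality — for plain conditional mutual information, for unique
information, or for general minInf terms within marginal-preserving families.
The *slack* (upper bound minus summed terms) is the test statistic: a
negative slack rejects the hypothesized hidden-variable causal structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .distributions import (DiscreteJointDistribution, _as_names,
                            _check_disjoint)
from .graphs import CausalDAG
from .optimize import MarginalFamily, MinInfTerm, mininf, unique_information
from .plans import IterationPlan, PlanInsert, build_plan

__all__ = [
    "InstrumentalSpec", "ChainPartition", "Group", "GroupCollection",
    "ICScenario", "Term", "InequalityResult",
    "eval_standard_instrumental", "eval_unique_instrumental",
    "build_chain_decomposition", "eval_combined",
    "validate_iteration_plan", "plan_from_independencies",
    "eval_mininf_instrumental", "eval_gd1", "eval_ic",
]

#: a violation call must exceed numerical slop by at least this much (bits)
DECISION_TOL = 1e-6


# ---------------------------------------------------------------------------
# role specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InstrumentalSpec:
    """Variable-role assignment for the instrumental inequality family.

    ``z`` is the (possibly multivariate) instrumental set, ``x`` the treatment
    whose entropy bounds the test, ``y`` the outcome block, ``b0`` the
    conditioning set of the instrumental independence Z ⊥ U | B0, with the
    optional partition ``b0 = b1 ∪ b2`` (unique-information form) and the
    outcome split ``y = y1 ∪ y2`` with ``ybar ⊆ y1`` (combined form). ``u``
    names the hidden block for graph validation and simulation-mode checks.
    """

    z: tuple[str, ...]
    x: tuple[str, ...]
    y: tuple[str, ...] = ()
    b0: tuple[str, ...] = ()
    b1: tuple[str, ...] | None = None
    b2: tuple[str, ...] | None = None
    u: tuple[str, ...] = ()
    y1: tuple[str, ...] | None = None
    y2: tuple[str, ...] | None = None
    ybar: tuple[str, ...] = ()

    def __init__(self, z, x, y=(), b0=(), b1=None, b2=None, u=(),
                 y1=None, y2=None, ybar=()):
        g = {"z": _as_names(z), "x": _as_names(x), "y": _as_names(y),
             "b0": _as_names(b0), "u": _as_names(u), "ybar": _as_names(ybar)}
        g["b1"] = None if b1 is None else _as_names(b1)
        g["b2"] = None if b2 is None else _as_names(b2)
        g["y1"] = None if y1 is None else _as_names(y1)
        g["y2"] = None if y2 is None else _as_names(y2)
        if (g["b1"] is None) != (g["b2"] is None):
            missing = "b1" if g["b1"] is None else "b2"
            g[missing] = tuple(n for n in g["b0"]
                               if n not in (g["b2"] or g["b1"] or ()))
        if g["b1"] is not None:
            if set(g["b1"]) | set(g["b2"]) != set(g["b0"]) or \
                    set(g["b1"]) & set(g["b2"]):
                raise ValueError("b1 and b2 must partition b0")
        if g["y1"] is not None or g["y2"] is not None:
            g["y1"] = g["y1"] or ()
            g["y2"] = g["y2"] or ()
            if set(g["y1"]) | set(g["y2"]) != set(g["y"]) or \
                    set(g["y1"]) & set(g["y2"]):
                raise ValueError("y1 and y2 must partition y")
        if not set(g["ybar"]) <= set(g["y1"] or ()):
            raise ValueError("ybar must be a subset of y1")
        _check_disjoint(Z=g["z"], X=g["x"], Y=g["y"], B0=g["b0"], U=g["u"])
        for k, v in g.items():
            object.__setattr__(self, k, v)


@dataclass(frozen=True)
class ChainPartition:
    """An ordered exclusive partition Z_1, ..., Z_r of the instrumental set."""
    parts: tuple[tuple[str, ...], ...]

    def __init__(self, parts: Sequence[Iterable[str]]):
        parts = tuple(_as_names(p) for p in parts)
        flat = [n for p in parts for n in p]
        if len(flat) != len(set(flat)):
            raise ValueError("partition parts must be disjoint")
        if any(not p for p in parts):
            raise ValueError("partition parts must be nonempty")
        object.__setattr__(self, "parts", parts)

    def prefix(self, j: int) -> tuple[str, ...]:
        """Z_[j-1] = Z_1 ∪ ... ∪ Z_(j-1)."""
        return tuple(n for p in self.parts[:j - 1] for n in p)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class Term:
    name: str
    value: float | None
    status: str = "exact"          # exact | convex-certified | multistart | failed
    provenance: str = ""
    constraint_violation: float = 0.0


@dataclass
class InequalityResult:
    upper_bound: float
    terms: list[Term]
    slack: float
    violated: bool
    decision_tol: float
    provenance: list[str] = field(default_factory=list)

    def term(self, name: str) -> Term:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "upper_bound": self.upper_bound,
            "terms": [{"name": t.name, "value": t.value, "status": t.status,
                       "provenance": t.provenance,
                       "constraint_violation": t.constraint_violation}
                      for t in self.terms],
            "slack": self.slack,
            "violated": bool(self.violated),
            "decision_tol": self.decision_tol,
            "provenance": self.provenance,
        }


def _assemble(upper: float, terms: list[Term],
              provenance: list[str]) -> InequalityResult:
    usable = [t.value for t in terms if t.value is not None]
    slack = upper - float(np.sum(usable)) if usable else upper
    worst_cv = max((t.constraint_violation for t in terms), default=0.0)
    tol = max(DECISION_TOL, 3.0 * worst_cv)
    return InequalityResult(upper_bound=upper, terms=terms, slack=slack,
                            violated=slack < -tol, decision_tol=tol,
                            provenance=provenance)


def _fmt(names: Iterable[str]) -> str:
    names = list(names)
    return ",".join(names) if names else "∅"


# ---------------------------------------------------------------------------
# instrumental inequalities
# ---------------------------------------------------------------------------

def eval_standard_instrumental(P: DiscreteJointDistribution,
                               spec: InstrumentalSpec) -> InequalityResult:
    """H(X|B0) >= I(Z;X|B0) + I(Z;Y|B0,X).

    Causally imposed whenever the structure yields Z ⊥ U | B0 and
    Z ⊥ Y | U, X, B0 with U hidden.
    """
    z, x, y, b0 = spec.z, spec.x, spec.y, spec.b0
    upper = P.conditional_entropy(x, b0)
    terms = [
        Term(f"I({_fmt(z)};{_fmt(x)}|{_fmt(b0)})",
             P.conditional_mutual_information(z, x, b0)),
        Term(f"I({_fmt(z)};{_fmt(y)}|{_fmt(b0)},{_fmt(x)})",
             P.conditional_mutual_information(z, y, tuple(b0) + tuple(x)),
             provenance="DP inequality from Z⊥Y|U,X,B0"),
    ]
    return _assemble(upper, terms, [f"upper bound H(X|B0) from Z⊥U|B0 "
                                    f"with B0={_fmt(b0)}"])


def eval_unique_instrumental(P: DiscreteJointDistribution,
                             spec: InstrumentalSpec,
                             **solver_kw) -> InequalityResult:
    """H(X|B0) >= I(Z;X|B0) + I(Z;Y\\\\B2|B1,X) with B0 = B1 ∪ B2.

    The second term is the unique information of Y with respect to the
    reference B2, licensed by the weaker independence Z ⊥ Y | U, X, B1 (B2
    excluded from the conditioning — useful when B2 contains colliders).
    """
    z, x, y, b0 = spec.z, spec.x, spec.y, spec.b0
    b1 = spec.b1 if spec.b1 is not None else ()
    b2 = spec.b2 if spec.b2 is not None else b0
    upper = P.conditional_entropy(x, b0)
    ui = unique_information(P, z, y, b2, tuple(b1) + tuple(x), **solver_kw)
    terms = [
        Term(f"I({_fmt(z)};{_fmt(x)}|{_fmt(b0)})",
             P.conditional_mutual_information(z, x, b0)),
        Term(f"I({_fmt(z)};{_fmt(y)}\\\\{_fmt(b2)}|{_fmt(b1)},{_fmt(x)})",
             None if ui.status == "failed" else ui.value, status=ui.status,
             provenance="unique-information DP from Z⊥Y|U,X,B1",
             constraint_violation=ui.constraint_violation),
    ]
    return _assemble(upper, terms, [f"upper bound H(X|B0) from Z⊥U|B0",
                                    f"reference predictor B2={_fmt(b2)}"])


def build_chain_decomposition(P: DiscreteJointDistribution,
                              spec: InstrumentalSpec,
                              partition: ChainPartition,
                              include_hidden: bool = True) -> list[Term]:
    """Chainlike decomposition of the nontestable lower bound:
    I(Z;X|B0) plus the terms I(Z_j; U | B0, X, Z_[j-1]), whose sum over j
    equals I(Z;U|B0,X) by the chain rule.

    The hidden terms are only computable in simulation mode (U present in P);
    in testable mode they are reported without values as placeholders for
    data-processing replacements.
    """
    z, x, b0, u = spec.z, spec.x, spec.b0, spec.u
    if set(z) != {n for p in partition.parts for n in p}:
        raise ValueError("partition must cover exactly Z")
    terms = [Term(f"I({_fmt(z)};{_fmt(x)}|{_fmt(b0)})",
                  P.conditional_mutual_information(z, x, b0))]
    if include_hidden and not set(u) <= set(P.variables.names):
        raise ValueError("include_hidden requires U in the distribution")
    for j, zj in enumerate(partition.parts, start=1):
        prefix = partition.prefix(j)
        cond = tuple(b0) + tuple(x) + prefix
        name = f"I({_fmt(zj)};{_fmt(u)}|{_fmt(cond)})"
        value = (P.conditional_mutual_information(zj, u, cond)
                 if include_hidden else None)
        terms.append(Term(name, value, status="exact" if include_hidden
                          else "nonestimable"))
    return terms


def eval_combined(P: DiscreteJointDistribution, spec: InstrumentalSpec,
                  **solver_kw) -> InequalityResult:
    """H(X|B0) >= I(Z;X|B0) + I(Z;Y1|B0,X) + I(Z;Y2\\\\{B2,Ȳ}|B1,X,Y1\\Ȳ).

    Combines one conditional-mutual-information data-processing step (for Y1)
    with one unique-information step (for Y2) whose reference {B2, Ȳ}
    removes exactly the colliders that the first step had to condition on.
    """
    if spec.y1 is None or spec.y2 is None:
        raise ValueError("combined inequality needs the y = {y1, y2} split")
    z, x, b0 = spec.z, spec.x, spec.b0
    b1 = spec.b1 if spec.b1 is not None else ()
    b2 = spec.b2 if spec.b2 is not None else b0
    y1, y2, ybar = spec.y1, spec.y2, spec.ybar
    y1_rest = tuple(n for n in y1 if n not in set(ybar))
    upper = P.conditional_entropy(x, b0)
    ref = tuple(b2) + tuple(ybar)
    o1 = tuple(b1) + tuple(x) + y1_rest
    ui = unique_information(P, z, y2, ref, o1, **solver_kw)
    terms = [
        Term(f"I({_fmt(z)};{_fmt(x)}|{_fmt(b0)})",
             P.conditional_mutual_information(z, x, b0)),
        Term(f"I({_fmt(z)};{_fmt(y1)}|{_fmt(b0)},{_fmt(x)})",
             P.conditional_mutual_information(z, y1, tuple(b0) + tuple(x)),
             provenance="DP inequality from Z⊥Y1|U,X,B0"),
        Term(f"I({_fmt(z)};{_fmt(y2)}\\\\{_fmt(ref)}|{_fmt(o1)})",
             None if ui.status == "failed" else ui.value, status=ui.status,
             provenance="unique-information DP from Z⊥Y2|U,X,B1,Y1\\Ȳ",
             constraint_violation=ui.constraint_violation),
    ]
    return _assemble(upper, terms, ["upper bound H(X|B0) from Z⊥U|B0"])


# ---------------------------------------------------------------------------
# iterative minInf instrumental inequalities
# ---------------------------------------------------------------------------

def validate_iteration_plan(plan: IterationPlan, graph: CausalDAG | None = None):
    """Report-style check of all structural invariants of a plan and of each
    step's licensing independence in the graph."""
    return plan.validate(graph)


def plan_from_independencies(graph: CausalDAG, spec: InstrumentalSpec,
                             insert_sequence: Sequence[PlanInsert | tuple],
                             part: Iterable[str] | None = None,
                             prefix: Iterable[str] = (),
                             merge: bool = True) -> IterationPlan:
    """Build the iteration plan for one partition part of the instrumental
    set: initial roles Z̄ = part (default: all of Z), Ū = U and
    E = {B0, X, Z_[i-1]}, then the requested inserts. Every requested
    independence must hold in the graph."""
    zbar0 = _as_names(part) if part is not None else spec.z
    e = tuple(spec.b0) + tuple(spec.x) + _as_names(prefix)
    return build_plan(e, zbar0, spec.u, insert_sequence, graph=graph,
                      merge=merge)


def eval_mininf_instrumental(P: DiscreteJointDistribution,
                             spec: InstrumentalSpec,
                             partition: ChainPartition,
                             plans: Sequence[IterationPlan | None],
                             graph: CausalDAG | None = None,
                             **solver_kw) -> InequalityResult:
    """H(X|B0) >= I(Z;X|B0) + sum over plan steps of the minInf terms
    min over Δ_P^(ij) of I_Q(Z̄_ij ; A_ij | E_i, A_i[j-1], Ž_i[j]),
    where Δ_P^(ij) preserves P(Z̄_ij, A_ij, B̄_ij) and P(Z̄_ik, C_ik), k <= j.

    ``plans[i]`` drives the insertions below the i-th chain term
    I(Z_i; U | B0, X, Z_[i-1]); entries may be None to skip a part. A failed
    minimization drops its term: every minInf term is nonnegative, so the
    bound weakens but never falsely rejects.
    """
    if len(plans) != len(partition.parts):
        raise ValueError("need one plan entry (possibly None) per partition part")
    if not any(p is not None and p.steps for p in plans):
        raise ValueError("at least one nonempty plan is required")
    z, x, b0 = spec.z, spec.x, spec.b0
    upper = P.conditional_entropy(x, b0)
    terms = [Term(f"I({_fmt(z)};{_fmt(x)}|{_fmt(b0)})",
                  P.conditional_mutual_information(z, x, b0))]
    provenance = ["upper bound H(X|B0) from Z⊥U|B0"]
    for i, (part, plan) in enumerate(zip(partition.parts, plans), start=1):
        if plan is None or not plan.steps:
            continue
        e_i = set(b0) | set(x) | set(partition.prefix(i))
        if plan.e != frozenset(e_i):
            raise ValueError(f"plan {i} has E={sorted(plan.e)}, expected "
                             f"{sorted(e_i)} = {{B0, X, Z_[i-1]}}")
        if graph is not None:
            report = plan.validate(graph)
            if not report.valid:
                raise ValueError(f"plan {i} invalid: {report.first_failure()}")
        for j, st in enumerate(plan.steps, start=1):
            preserved = plan.preserved_marginals(j, include_hidden=False)
            fam = MarginalFamily(P, preserved)
            cond = plan.objective_conditioning(j)
            term = MinInfTerm(fam, tuple(sorted(st.zbar)), tuple(sorted(st.a)),
                              tuple(sorted(cond)))
            res = mininf(term, **solver_kw)
            name = (f"min I({_fmt(sorted(st.zbar))};{_fmt(sorted(st.a))}|"
                    f"{_fmt(sorted(cond))}) over Δ_P^({i},{j})")
            terms.append(Term(
                name, None if res.status == "failed" else res.value,
                status=res.status,
                provenance=f"minInf DP from {_fmt(sorted(st.zbar))}⊥"
                           f"{_fmt(sorted(st.a))}|{_fmt(sorted(st.ubar | st.bbar))}; "
                           f"preserves {[sorted(s) for s in preserved]}",
                constraint_violation=res.constraint_violation))
    return _assemble(upper, terms, provenance)


# ---------------------------------------------------------------------------
# groups-decomposition (GD1) inequalities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Group:
    """One group B_i = {V_i, U_i} with its independence partition
    (B_i^(1), B_i^(2)) and an optional observable data-processing proxy
    (licensed by Y ⊥ proxy | Z, B_i)."""
    members: tuple[str, ...]
    part1: tuple[str, ...] | None = None
    part2: tuple[str, ...] = ()
    proxy: tuple[str, ...] = ()

    def __init__(self, members, part1=None, part2=(), proxy=()):
        members = _as_names(members)
        part1 = _as_names(part1) if part1 is not None else members
        part2 = _as_names(part2)
        if set(part1) | set(part2) != set(members) or set(part1) & set(part2):
            raise ValueError("(part1, part2) must partition the group")
        object.__setattr__(self, "members", members)
        object.__setattr__(self, "part1", part1)
        object.__setattr__(self, "part2", part2)
        object.__setattr__(self, "proxy", _as_names(proxy))


@dataclass(frozen=True)
class GroupCollection:
    """Target Y, conditioning Z, and overlapping groups B_1..B_n."""
    y: tuple[str, ...]
    z: tuple[str, ...]
    groups: tuple[Group, ...]
    hidden: frozenset[str] = frozenset()

    def __init__(self, y, z, groups, hidden=()):
        object.__setattr__(self, "y", _as_names(y))
        object.__setattr__(self, "z", _as_names(z))
        object.__setattr__(self, "groups", tuple(groups))
        object.__setattr__(self, "hidden", frozenset(_as_names(hidden)))

    def overlap_degree(self, i: int) -> int:
        """d_Bi = 1 + number of other groups intersecting B_i."""
        own = set(self.groups[i].members)
        return 1 + sum(1 for j, g in enumerate(self.groups)
                       if j != i and own & set(g.members))


def eval_gd1(P: DiscreteJointDistribution, gc: GroupCollection,
             testable_only: bool = False,
             graph: CausalDAG | None = None,
             indep_tol: float = 1e-9) -> InequalityResult:
    """GD1 inequality: H(Y|Z) >= sum_i (1/d_Bi) I(Y; B_i | Z).

    Requires the pairwise group independencies
    B_i^(1) ⊥ B_j^(1) \\ B_i^(1) | Z and B_i^(2) ⊥ B_j \\ B_i^(2) | B_i^(1), Z
    for all i != j, verified on P (simulation mode) or on a supplied graph.
    In testable mode each group's hidden members are dropped,
    I(Y;B_i|Z) -> I(Y;V_i|Z) (+ I(Y;proxy|Z,V_i) when the group declares an
    observable data-processing proxy).
    """
    y, z = gc.y, gc.z
    checker = _IndependenceChecker(P, graph, gc.hidden, indep_tol)
    for i, gi in enumerate(gc.groups):
        for j, gj in enumerate(gc.groups):
            if i == j:
                continue
            other1 = tuple(n for n in gj.part1 if n not in set(gi.part1))
            if other1 and not checker(gi.part1, other1, z):
                raise ValueError(
                    f"group independence B{i + 1}^(1) ⊥ B{j + 1}^(1)\\B{i + 1}^(1)"
                    f" | Z fails")
            other = tuple(n for n in gj.members if n not in set(gi.part2))
            if gi.part2 and other and not checker(
                    gi.part2, other, tuple(gi.part1) + tuple(z)):
                raise ValueError(
                    f"group independence B{i + 1}^(2) ⊥ B{j + 1}\\B{i + 1}^(2)"
                    f" | B{i + 1}^(1),Z fails")
    upper = P.conditional_entropy(y, z)
    terms = []
    for i, g in enumerate(gc.groups):
        d = gc.overlap_degree(i)
        w = 1.0 / d
        if testable_only:
            v = tuple(n for n in g.members if n not in gc.hidden)
            value = w * P.conditional_mutual_information(y, v, z) if v else 0.0
            name = f"(1/{d})·I({_fmt(y)};{_fmt(v)}|{_fmt(z)})"
            if g.proxy:
                if not checker(y, g.proxy, tuple(z) + tuple(g.members)):
                    raise ValueError(
                        f"proxy for group {i + 1} not licensed: "
                        f"Y ⊥ {g.proxy} | Z,B_{i + 1} fails")
                value += w * P.conditional_mutual_information(
                    y, g.proxy, tuple(z) + v)
                name += f" + (1/{d})·I({_fmt(y)};{_fmt(g.proxy)}|{_fmt(z)},{_fmt(v)})"
            terms.append(Term(name, value, provenance="testable GD1 group term"))
        else:
            if not set(g.members) <= set(P.variables.names):
                raise ValueError(f"group {i + 1} members missing from P "
                                 f"(simulation mode needs hidden variables)")
            terms.append(Term(
                f"(1/{d})·I({_fmt(y)};{_fmt(g.members)}|{_fmt(z)})",
                w * P.conditional_mutual_information(y, g.members, z)))
    return _assemble(upper, terms, ["GD1 group decomposition"])


class _IndependenceChecker:
    def __init__(self, P, graph, hidden, tol):
        self.P, self.graph, self.hidden, self.tol = P, graph, hidden, tol

    def __call__(self, a, b, c) -> bool:
        names = set(_as_names(a)) | set(_as_names(b)) | set(_as_names(c))
        if names <= set(self.P.variables.names):
            return self.P.is_conditionally_independent(a, b, c, tol=self.tol)
        if self.graph is not None:
            return self.graph.d_separated(a, b, c)
        raise ValueError("cannot verify independence: variables missing from "
                         "the distribution and no graph supplied")


# ---------------------------------------------------------------------------
# information causality (IC) inequality
# ---------------------------------------------------------------------------

@dataclass
class ICScenario:
    """The mutually-exclusive-observability marginal scenario of the IC
    inequality: only the marginals p(X, M, Y_i) are observable."""

    x_vars: tuple[str, ...]
    m: tuple[str, ...]
    y_vars: tuple[str, ...]
    marginals: list[DiscreteJointDistribution]
    u: tuple[str, ...] = ()
    joint: DiscreteJointDistribution | None = None

    def __init__(self, x_vars, m, y_vars, marginals, u=(), joint=None,
                 consistency_tol: float = 1e-9):
        x_vars, m, y_vars = _as_names(x_vars), _as_names(m), _as_names(y_vars)
        if len(marginals) != len(y_vars):
            raise ValueError("need exactly one marginal per Y_i")
        base = None
        for yi, dist in zip(y_vars, marginals):
            need = set(x_vars) | set(m) | {yi}
            if not need <= set(dist.variables.names):
                raise ValueError(f"marginal for {yi} missing required variables")
            xm = dist.marginalize(set(x_vars) | set(m)).permuted(
                tuple(x_vars) + tuple(m))
            if base is None:
                base = xm
            elif float(np.abs(base.probs - xm.probs).sum()) > consistency_tol:
                raise ValueError("marginals disagree on p(X, M)")
        self.x_vars, self.m, self.y_vars = x_vars, m, y_vars
        self.marginals = list(marginals)
        self.u = _as_names(u)
        self.joint = joint

    @classmethod
    def from_joint(cls, P: DiscreteJointDistribution, x_vars, m, y_vars,
                   u=()) -> "ICScenario":
        x_vars, m, y_vars = _as_names(x_vars), _as_names(m), _as_names(y_vars)
        margs = [P.marginalize(set(x_vars) | set(m) | {yi}) for yi in y_vars]
        return cls(x_vars, m, y_vars, margs, u=u, joint=P)


def eval_ic(scn: ICScenario, include_hidden: bool = False) -> InequalityResult:
    """Information Causality: H(M) - H(X) + sum_i H(X_i) >=
    I(X1;M) + sum_{i>=2} I(X_i;X1,M) + I(X1;Y1|M) + sum_{i>=2} I(X_i;Y_i|X1,M).

    Every term is computed from the observable marginals p(X, M, Y_i) alone.
    With ``include_hidden`` (simulation mode, full joint required) the
    intermediate nontestable terms I(X1;U|M,Y1) and I(X_i;U|X1,M,Y_i) are
    appended, exhibiting the lower bound before the hidden block is dropped.
    """
    x, m, ys = scn.x_vars, scn.m, scn.y_vars
    x1, rest = x[0], x[1:]
    base = scn.marginals[0]
    upper = (base.entropy(m) - base.entropy(x)
             + sum(base.entropy([xi]) for xi in x))
    terms = [Term(f"I({x1};{_fmt(m)})", base.mutual_information([x1], m),
                  provenance="from p(X,M)")]
    for xi in rest:
        terms.append(Term(f"I({xi};{x1},{_fmt(m)})",
                          base.mutual_information([xi], (x1,) + tuple(m)),
                          provenance="from p(X,M)"))
    terms.append(Term(
        f"I({x1};{ys[0]}|{_fmt(m)})",
        scn.marginals[0].conditional_mutual_information([x1], [ys[0]], m),
        provenance=f"DP from X1⊥Y1|U,M; from p(X,M,{ys[0]})"))
    for xi, yi, dist in zip(rest, ys[1:], scn.marginals[1:]):
        terms.append(Term(
            f"I({xi};{yi}|{x1},{_fmt(m)})",
            dist.conditional_mutual_information([xi], [yi], (x1,) + tuple(m)),
            provenance=f"DP from Xi⊥Yi|U,M,X1; from p(X,M,{yi})"))
    if include_hidden:
        if scn.joint is None or not set(scn.u) <= set(scn.joint.variables.names):
            raise ValueError("include_hidden requires the full joint with U")
        P = scn.joint
        terms.append(Term(
            f"I({x1};{_fmt(scn.u)}|{_fmt(m)},{ys[0]})",
            P.conditional_mutual_information([x1], scn.u, tuple(m) + (ys[0],)),
            status="nonestimable"))
        for xi, yi in zip(rest, ys[1:]):
            terms.append(Term(
                f"I({xi};{_fmt(scn.u)}|{x1},{_fmt(m)},{yi})",
                P.conditional_mutual_information([xi], scn.u,
                                                 (x1,) + tuple(m) + (yi,)),
                status="nonestimable"))
    return _assemble(upper, terms, ["upper bound from X⊥U and basic "
                                    "entropy properties"])
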