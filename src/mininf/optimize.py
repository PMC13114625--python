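"""Constrained minimum-information (minInf) terms.

A minInf term is the minimum of a conditional mutual information
``I_Q(target ; predictor | conditioning)`` over the family of joint
distributions Q that preserve a stated list of marginals of a reference
distribution P. Preserving marginals is an affine constraint on the joint
table, so each instance is a smooth minimization over a polytope.

The unique-information pattern — exactly two preserved marginals, both
containing the target, with the objective conditioning on everything the
predictor-free marginal adds — is a convex program and is certified as such.
General instances are non-convex and solved by multistart local minimization
(SLSQP with analytic gradients), with feasible starts produced by iterative
proportional fitting (IPF).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import xlogy

from .distributions import (DiscreteJointDistribution, VariableSet, _as_names,
                            _check_disjoint)

__all__ = [
    "MarginalFamily", "MinInfTerm", "MinInfResult", "mininf",
    "unique_information", "brute_force_mininf", "verify_dp_mininf",
    "DPVerificationReport", "extend_with_cpt", "extend_with_conditional",
]

_LOG2 = np.log(2.0)
#: accepted L1 deviation of a preserved marginal in a solution
CONSTRAINT_TOL = 1e-8


# ---------------------------------------------------------------------------
# joint-table composition helpers
# ---------------------------------------------------------------------------

def extend_with_cpt(base: DiscreteJointDistribution, name: str, card: int,
                    parents: Sequence[str], cpt: np.ndarray
                    ) -> DiscreteJointDistribution:
    """Append variable ``name`` drawn from ``cpt`` given ``parents`` ⊆ base.

    ``cpt`` has shape (*parent cardinalities in base order, card) with rows
    summing to 1. The result is exact: a product of the base table and the
    conditional table.
    """
    parents = [n for n in base.variables.names if n in set(parents)]
    if len(parents) != len(set(_as_names(parents))):
        raise ValueError("parents must be distinct members of the base scope")
    cpt = np.asarray(cpt, dtype=float)
    expected = tuple(base.variables.cardinality(p) for p in parents) + (card,)
    if cpt.shape != expected:
        raise ValueError(f"cpt shape {cpt.shape} != expected {expected}")
    if not np.allclose(cpt.sum(axis=-1), 1.0, atol=1e-9):
        raise ValueError("cpt rows must sum to 1")
    # broadcast the cpt over the non-parent axes of the base table
    shape = [base.variables.cardinality(n) if n in parents else 1
             for n in base.variables.names] + [card]
    order = np.argsort([parents.index(n) for n in base.variables.names
                        if n in parents]) if parents else []
    expanded = cpt.reshape([base.variables.cardinality(p) for p in parents] + [card])
    del order  # parents already follow base order
    expanded = expanded.reshape(shape)
    probs = base.probs[..., None] * expanded
    vs = base.variables.union(VariableSet([name], [card]))
    return DiscreteJointDistribution(vs, probs, _validate=False)


def extend_with_conditional(base: DiscreteJointDistribution,
                            source: DiscreteJointDistribution,
                            new: Iterable[str], given: Iterable[str]
                            ) -> DiscreteJointDistribution:
    """Extend ``base`` with variables ``new`` drawn from source's P(new|given).

    ``given`` must be contained in both scopes. Conditioning states with zero
    mass in the source get a uniform conditional (they carry zero mass in any
    base whose ``given``-marginal matches the source's).
    """
    new_n = [n for n in source.variables.names if n in set(_as_names(new))]
    given_n = [n for n in base.variables.names if n in set(_as_names(given))]
    joint = source.marginalize(set(new_n) | set(given_n)).permuted(given_n + new_n)
    k = len(given_n)
    denom = joint.probs.sum(axis=tuple(range(k, joint.probs.ndim)), keepdims=True)
    n_states = int(np.prod(joint.probs.shape[k:])) if joint.probs.ndim > k else 1
    cpt = np.where(denom > 0, joint.probs / np.where(denom > 0, denom, 1.0),
                   1.0 / n_states)
    out = base
    # append the new block one variable at a time is wasteful; do it in one go
    shape = [base.variables.cardinality(n) if n in given_n else 1
             for n in base.variables.names] + list(joint.probs.shape[k:])
    expanded = cpt.reshape(shape)
    probs = base.probs.reshape(base.probs.shape + (1,) * (joint.probs.ndim - k)) * expanded
    vs = base.variables.union(VariableSet(
        new_n, [source.variables.cardinality(n) for n in new_n]))
    out = DiscreteJointDistribution(vs, probs, _validate=False)
    return out


# ---------------------------------------------------------------------------
# marginal-preserving families
# ---------------------------------------------------------------------------

class MarginalFamily:
    """The family Δ_P of joint distributions over ``scope`` that preserve the
    marginals of ``reference`` on each subset in ``preserved``.

    The reference (marginalized to the scope) is itself a member, so the
    family is never empty. Preserved subsets contained in another preserved
    subset are redundant and collapsed away.
    """

    def __init__(self, reference: DiscreteJointDistribution,
                 preserved: Sequence[Iterable[str]],
                 scope: Iterable[str] | None = None):
        pres = [frozenset(_as_names(s)) for s in preserved]
        scope_names = (set(_as_names(scope)) if scope is not None
                       else set().union(*pres) if pres else set(reference.variables.names))
        if not scope_names <= set(reference.variables.names):
            raise ValueError("reference does not cover the requested scope")
        for s in pres:
            if not s <= scope_names:
                raise ValueError(f"preserved subset {sorted(s)} outside scope")
        # drop redundant (contained) subsets, keep deterministic order
        maximal = [s for s in pres if not any(s < t for t in pres)]
        seen: list[frozenset] = []
        for s in maximal:
            if s not in seen:
                seen.append(s)
        self.reference = reference
        self.scope = reference.variables.subset(scope_names)
        self.preserved = seen
        self._cards = tuple(self.scope.cardinalities)
        self._n = int(np.prod(self._cards)) if self._cards else 1
        coords = np.indices(self._cards).reshape(len(self._cards), -1) \
            if self._cards else np.zeros((0, 1), dtype=int)
        self._coords = coords
        self._subset_cache: dict[frozenset, tuple[np.ndarray, int]] = {}
        # per preserved subset: cell->state index map and target marginal
        ref_scope = reference.marginalize(self.scope).permuted(self.scope.names)
        self._ref_scope = ref_scope
        self._targets = []
        for s in self.preserved:
            idx, size = self._subset_index(s)
            t = np.bincount(idx, ref_scope.probs.ravel(), minlength=size)
            self._targets.append(t)

    def _subset_index(self, names: Iterable[str]) -> tuple[np.ndarray, int]:
        key = frozenset(_as_names(names))
        if key not in self._subset_cache:
            axes = [i for i, n in enumerate(self.scope.names) if n in key]
            if not axes:
                idx = np.zeros(self._n, dtype=np.int64)
                size = 1
            else:
                dims = [self._cards[i] for i in axes]
                idx = np.ravel_multi_index([self._coords[i] for i in axes], dims)
                size = int(np.prod(dims))
            self._subset_cache[key] = (np.asarray(idx, dtype=np.int64), size)
        return self._subset_cache[key]

    @property
    def n_cells(self) -> int:
        return self._n

    @property
    def is_singleton(self) -> bool:
        """True when some preserved subset pins the whole scope."""
        return any(s == frozenset(self.scope.names) for s in self.preserved)

    def reference_member(self) -> DiscreteJointDistribution:
        return self._ref_scope

    def constraint_matrix(self, reduce: bool = True
                          ) -> tuple[np.ndarray, np.ndarray]:
        """Stacked equality constraints A q = b (includes normalization).

        Marginal constraints overlap (shared sub-marginals, normalization),
        so by default the system is reduced to a maximal independent row set
        via pivoted QR; the dropped rows are linear consequences.
        """
        rows = [np.ones((1, self._n))]
        rhs = [np.ones(1)]
        for s, t in zip(self.preserved, self._targets):
            idx, size = self._subset_index(s)
            m = np.zeros((size, self._n))
            m[idx, np.arange(self._n)] = 1.0
            rows.append(m)
            rhs.append(t)
        a_mat, b_vec = np.vstack(rows), np.concatenate(rhs)
        if reduce:
            from scipy.linalg import qr

            _, r, piv = qr(a_mat.T, mode="economic", pivoting=True)
            diag = np.abs(np.diag(r))
            rank = int((diag > max(a_mat.shape) * np.finfo(float).eps
                        * (diag[0] if diag.size else 1.0)).sum())
            keep = np.sort(piv[:rank])
            a_mat, b_vec = a_mat[keep], b_vec[keep]
        return a_mat, b_vec

    def violation(self, q: np.ndarray) -> float:
        """Max over preserved subsets of the L1 marginal deviation of q."""
        q = np.asarray(q, dtype=float).ravel()
        worst = abs(q.sum() - 1.0)
        for s, t in zip(self.preserved, self._targets):
            idx, size = self._subset_index(s)
            worst = max(worst, float(np.abs(np.bincount(idx, q, minlength=size) - t).sum()))
        return worst

    def ipf_project(self, q0: np.ndarray, max_sweeps: int = 500,
                    tol: float = 1e-10) -> np.ndarray:
        """Iterative proportional fitting of q0 onto the preserved marginals.

        Converges for any strictly positive start since all preserved
        marginals come from one common reference.
        """
        q = np.asarray(q0, dtype=float).ravel().copy()
        q /= q.sum()
        for _ in range(max_sweeps):
            delta = 0.0
            for s, t in zip(self.preserved, self._targets):
                idx, size = self._subset_index(s)
                m = np.bincount(idx, q, minlength=size)
                ratio = np.divide(t, m, out=np.ones_like(t), where=m > 0)
                qn = q * ratio[idx]
                total = qn.sum()
                if total > 0:
                    qn /= total
                delta = max(delta, float(np.abs(qn - q).sum()))
                q = qn
            if delta < tol:
                break
        return q

    def member(self, q: np.ndarray) -> DiscreteJointDistribution:
        q = np.clip(np.asarray(q, dtype=float).ravel(), 0.0, None)
        q = q / q.sum()
        return DiscreteJointDistribution(self.scope, q.reshape(self._cards),
                                         _validate=False)


@dataclass(frozen=True)
class MinInfTerm:
    """The quantity min_{Q ∈ family} I_Q(target ; predictor | conditioning)."""

    family: MarginalFamily
    target: tuple[str, ...]
    predictor: tuple[str, ...]
    conditioning: tuple[str, ...] = ()

    def __init__(self, family, target, predictor, conditioning=()):
        t, p, c = _as_names(target), _as_names(predictor), _as_names(conditioning)
        _check_disjoint(target=t, predictor=p, conditioning=c)
        for role, names in (("target", t), ("predictor", p), ("conditioning", c)):
            if not set(names) <= set(family.scope.names):
                raise ValueError(f"{role} {names} not within family scope")
        object.__setattr__(self, "family", family)
        object.__setattr__(self, "target", t)
        object.__setattr__(self, "predictor", p)
        object.__setattr__(self, "conditioning", c)


@dataclass
class MinInfResult:
    value: float
    argmin: DiscreteJointDistribution
    constraint_violation: float
    status: str
    restarts_used: int
    start_values: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# objective: I(T ; P | C) as a function of the flat joint table
# ---------------------------------------------------------------------------

class _CMIObjective:
    def __init__(self, family: MarginalFamily, target, predictor, conditioning):
        t, p, c = set(target), set(predictor), set(conditioning)
        self._groups = []
        for names, sign in ((t | p | c, +1.0), (c, +1.0), (t | c, -1.0), (p | c, -1.0)):
            idx, size = family._subset_index(names)
            self._groups.append((idx, size, sign))

    def value(self, q: np.ndarray) -> float:
        q = np.asarray(q, dtype=float).ravel()
        total = 0.0
        for idx, size, sign in self._groups:
            m = np.bincount(idx, q, minlength=size)
            total += sign * float(xlogy(m, m).sum())
        return total / _LOG2

    def grad(self, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float).ravel()
        g = np.zeros_like(q)
        for idx, size, sign in self._groups:
            m = np.bincount(idx, q, minlength=size)
            g += sign * np.log(np.maximum(m, 1e-18))[idx]
        return g / _LOG2

    def value_batch(self, q: np.ndarray) -> np.ndarray:
        """Objective for a batch of flat tables, shape (B, n)."""
        out = np.zeros(q.shape[0])
        for idx, size, sign in self._groups:
            m = np.zeros((q.shape[0], size))
            np.add.at(m.T, idx, q.T)
            out += sign * xlogy(m, m).sum(axis=1)
        return out / _LOG2


def _is_unique_information_pattern(term: MinInfTerm) -> bool:
    """Eq-5 structure: two preserved marginals sharing the target, with the
    objective conditioning on everything the predictor-free one adds."""
    fam = term.family
    if fam.is_singleton and len(fam.preserved) == 1:
        return True
    if len(fam.preserved) != 2:
        return False
    t, p, c = set(term.target), set(term.predictor), set(term.conditioning)
    for s1, s2 in ((fam.preserved[0], fam.preserved[1]),
                   (fam.preserved[1], fam.preserved[0])):
        if (t <= (s1 & s2) and p == set(s1) - set(s2)
                and c == set(s2) - t
                and (s1 | s2) == set(fam.scope.names)):
            return True
    return False


def _ci_coupling_start(fam: MarginalFamily) -> np.ndarray | None:
    """For two preserved marginals S1, S2: the member with S1\\S2 ⊥ S2\\S1
    given S1 ∩ S2 (exactly feasible; for the unique-information pattern it
    attains the I(target;predictor|O1) upper bound of the sandwich)."""
    if len(fam.preserved) != 2:
        return None
    s1, s2 = fam.preserved
    base = fam._ref_scope.marginalize(s2)
    joint = extend_with_conditional(base, fam._ref_scope, sorted(s1 - s2),
                                    sorted(s1 & s2))
    return joint.permuted(fam.scope.names).probs.ravel()


def mininf(term: MinInfTerm, tolerance: float = 1e-9, restarts: int = 8,
           seed: int = 0,
           extra_starts: Sequence[np.ndarray | DiscreteJointDistribution] = ()
           ) -> MinInfResult:
    """Minimize I_Q(target; predictor | conditioning) within the family.

    Starts comprise the reference member, the IPF projection of the uniform
    table (independent-product start), the conditional-independence coupling
    when two marginals are preserved, any caller-supplied feasible points
    (``extra_starts``; projected onto the constraints first), and seeded
    random Dirichlet draws projected by IPF up to ``restarts`` total. The
    reported value is the best over all starts and polished solutions,
    clipped at zero.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    fam = term.family
    obj = _CMIObjective(fam, term.target, term.predictor, term.conditioning)
    convex = _is_unique_information_pattern(term)

    ref_q = fam._ref_scope.probs.ravel().copy()
    if fam.is_singleton:
        val = max(obj.value(ref_q), 0.0)
        return MinInfResult(val, fam.member(ref_q), 0.0, "convex-certified", 0, [val])

    starts: list[np.ndarray] = [ref_q]
    starts.append(fam.ipf_project(np.full(fam.n_cells, 1.0 / fam.n_cells)))
    ci = _ci_coupling_start(fam)
    if ci is not None:
        starts.append(ci)
    for extra in extra_starts:
        q = extra.permuted(fam.scope.names).probs.ravel() \
            if isinstance(extra, DiscreteJointDistribution) else np.asarray(extra).ravel()
        starts.append(fam.ipf_project(np.maximum(q, 1e-300)))
    if not convex:
        rng = np.random.default_rng(seed)
        while len(starts) < restarts:
            draw = rng.dirichlet(np.ones(fam.n_cells))
            starts.append(fam.ipf_project(draw))

    a_mat, b_vec = fam.constraint_matrix()
    constraints = [{"type": "eq", "fun": lambda q: a_mat @ q - b_vec,
                    "jac": lambda q: a_mat}]
    bounds = [(0.0, 1.0)] * fam.n_cells

    best_q, best_val = None, np.inf
    start_vals = []
    n_runs = 0
    for q0 in starts:
        v0 = obj.value(q0)
        start_vals.append(v0)
        if fam.violation(q0) <= CONSTRAINT_TOL and v0 < best_val:
            best_q, best_val = q0, v0
        res = minimize(obj.value, q0, jac=obj.grad, method="SLSQP",
                       bounds=bounds, constraints=constraints,
                       options={"ftol": 1e-12, "maxiter": 400})
        n_runs += 1
        if res.x is not None and fam.violation(res.x) <= CONSTRAINT_TOL:
            v = obj.value(res.x)
            if v < best_val:
                best_q, best_val = res.x, v
        if convex and best_q is not None and best_val <= tolerance:
            break  # objective is bounded below by 0; nothing left to gain
    if best_q is None:
        return MinInfResult(float("nan"), fam.member(ref_q),
                            fam.violation(ref_q), "failed", n_runs, start_vals)
    status = "convex-certified" if convex else "multistart"
    value = 0.0 if best_val < tolerance else float(best_val)
    return MinInfResult(value, fam.member(best_q), fam.violation(best_q),
                        status, n_runs, start_vals)


# ---------------------------------------------------------------------------
# unique information (maximum-entropy / minimum-information form)
# ---------------------------------------------------------------------------

def unique_information(P: DiscreteJointDistribution, Z, D1, D2, O1=(),
                       **solver_kw) -> MinInfResult:
    """I(Z ; D1 \\\\ D2 | O1): information about Z carried by predictor D1
    and not by the reference predictor D2, conditioned on O1.

    Computed as the minimum of I_Q(Z; D1 | D2, O1) over distributions Q on
    {Z, D1, D2, O1} preserving P(Z, D1, O1) and P(Z, D2, O1). Sandwiched by
    0 <= UI <= min{I(Z;D1|O1), I(Z;D1|D2,O1)}.
    """
    z, d1, d2, o1 = _as_names(Z), _as_names(D1), _as_names(D2), _as_names(O1)
    _check_disjoint(Z=z, D1=d1, D2=d2, O1=o1)
    scope = set(z) | set(d1) | set(d2) | set(o1)
    fam = MarginalFamily(P, [set(z) | set(d1) | set(o1),
                             set(z) | set(d2) | set(o1)], scope=scope)
    term = MinInfTerm(fam, z, d1, tuple(d2) + tuple(o1))
    return mininf(term, **solver_kw)


# ---------------------------------------------------------------------------
# sampling oracle
# ---------------------------------------------------------------------------

def brute_force_mininf(term: MinInfTerm, samples: int = 50_000,
                       seed: int = 0) -> float:
    """Upper-bound the minInf value by scanning random feasible points.

    Feasible points are IPF projections of random simplex draws (a mix of
    Dirichlet concentrations for boundary and interior coverage, starting
    from the barycenter, plus multiplicative perturbations of the incumbent
    with shrinking strength) together with the reference member. The running
    minimum is non-increasing in ``samples`` for a fixed seed chain. Only
    admissible for tiny scopes.
    """
    fam = term.family
    if len(fam.scope) > 4 or any(c > 3 for c in fam.scope.cardinalities):
        raise ValueError("oracle admissible only for <=4 variables of cardinality <=3")
    obj = _CMIObjective(fam, term.target, term.predictor, term.conditioning)
    rng = np.random.default_rng(seed)
    n = fam.n_cells
    best_q = fam._ref_scope.probs.ravel()
    best = obj.value(best_q)

    def consider(batch: np.ndarray) -> None:
        nonlocal best, best_q
        proj = _ipf_batch(fam, batch)
        vals = obj.value_batch(proj)
        ok = _violation_batch(fam, proj) <= 1e-7
        vals = np.where(ok, vals, np.inf)
        i = int(np.argmin(vals))
        if vals[i] < best:
            best, best_q = float(vals[i]), proj[i]

    consider(np.full((1, n), 1.0 / n))  # barycenter first
    done = 1
    batch_size = 2000
    concentrations = (0.2, 1.0, 3.0)
    k = 0
    while done < samples:
        b = min(batch_size, samples - done)
        alpha = concentrations[k % len(concentrations)]
        if k % 4 == 3 and np.isfinite(best):
            scale = 0.5 / (1 + k / 8)
            noise = np.exp(scale * rng.standard_normal((b, n)))
            batch = np.maximum(best_q[None, :], 1e-12) * noise
            batch /= batch.sum(axis=1, keepdims=True)
        else:
            batch = rng.dirichlet(np.full(n, alpha), size=b)
        consider(batch)
        done += b
        k += 1
    return max(best, 0.0)


def _ipf_batch(fam: MarginalFamily, q: np.ndarray, sweeps: int = 200,
               tol: float = 1e-10) -> np.ndarray:
    q = np.asarray(q, dtype=float).copy()
    q /= q.sum(axis=1, keepdims=True)
    mats = []
    for s, t in zip(fam.preserved, fam._targets):
        idx, size = fam._subset_index(s)
        m = np.zeros((fam.n_cells, size))
        m[np.arange(fam.n_cells), idx] = 1.0
        mats.append((m, idx, t))
    for _ in range(sweeps):
        delta = 0.0
        for m, idx, t in mats:
            marg = q @ m
            ratio = np.divide(t[None, :], marg, out=np.ones_like(marg),
                              where=marg > 0)
            qn = q * ratio[:, idx]
            qn /= qn.sum(axis=1, keepdims=True)
            delta = max(delta, float(np.abs(qn - q).sum(axis=1).max()))
            q = qn
        if delta < tol:
            break
    return q


def _violation_batch(fam: MarginalFamily, q: np.ndarray) -> np.ndarray:
    worst = np.abs(q.sum(axis=1) - 1.0)
    for s, t in zip(fam.preserved, fam._targets):
        idx, size = fam._subset_index(s)
        m = np.zeros((fam.n_cells, size))
        m[np.arange(fam.n_cells), idx] = 1.0
        worst = np.maximum(worst, np.abs(q @ m - t[None, :]).sum(axis=1))
    return worst


# ---------------------------------------------------------------------------
# the minInf data processing inequality (predictor-side DP)
# ---------------------------------------------------------------------------

@dataclass
class DPVerificationReport:
    min_dd: float       # min over Δ_P^DD' of I(Z; D, D', E2 | E)
    min_d: float        # min over Δ_P^D  of I(Z; D, E2 | E)
    min_dp: float       # min over Δ_P^D' of I(Z; D', E2 | E)
    equality_gap: float     # |min_dd - min_d|
    dp_slack: float         # min_d - min_dp (should be >= -tol)
    equality_holds: bool
    dp_holds: bool
    tolerance: float


def verify_dp_mininf(P: DiscreteJointDistribution, Z, D, Dp, E, E2=(),
                     O: Sequence[Iterable[str]] | None = None,
                     tol: float = 2e-6, precondition_tol: float = 1e-9,
                     restarts: int = 8, seed: int = 0) -> DPVerificationReport:
    """Verify the minInf data processing inequality in the predictor slot.

    With Z ⊥ D' | D, O1 in P, the minimum of I(Z; D, D', E2 | E) over the
    family preserving P(Z, D, D', O1) (plus P(Z, Oi), i >= 2) equals the
    minimum of I(Z; D, E2 | E) over the family preserving P(Z, D, O1) (plus
    P(Z, Oi)), and bounds the analogous minimum with D' in place of D.

    The three solves are cross-seeded with the constructive witnesses from
    the proof — the lift Q̄ = P(D'|D,O1)·Q* of one argmin and marginal
    projections of the other — so the asserted relations are checked at
    solver accuracy rather than at the mercy of local minima.
    """
    z, d, dp = _as_names(Z), _as_names(D), _as_names(Dp)
    e, e2 = _as_names(E), _as_names(E2)
    _check_disjoint(Z=z, D=d, Dp=dp, E=e, E2=e2)
    o_sets = [frozenset(_as_names(s)) for s in (O if O is not None else [set(e)])]
    if not o_sets:
        raise ValueError("O must contain at least O1")
    o1 = o_sets[0]
    if not all(s <= set(e) | set(e2) for s in o_sets):
        raise ValueError("every Oi must be a subset of {E, E2}")
    pre = P.conditional_mutual_information(z, dp, set(d) | o1)
    if pre > precondition_tol:
        raise ValueError(
            f"precondition Z ⊥ D' | D,O1 fails: I = {pre:.3e} bits")

    zs, ds, dps = set(z), set(d), set(dp)
    tail = [zs | s for s in o_sets[1:]]
    scope_dd = zs | ds | dps | set(e) | set(e2)
    scope_d = zs | ds | set(e) | set(e2)
    scope_dp = zs | dps | set(e) | set(e2)
    fam_dd = MarginalFamily(P, [zs | ds | dps | o1] + tail, scope=scope_dd)
    fam_d = MarginalFamily(P, [zs | ds | o1] + tail, scope=scope_d)
    fam_dp = MarginalFamily(P, [zs | dps | o1] + tail, scope=scope_dp)
    t_dd = MinInfTerm(fam_dd, z, tuple(d) + tuple(dp) + tuple(e2), e)
    t_d = MinInfTerm(fam_d, z, tuple(d) + tuple(e2), e)
    t_dp = MinInfTerm(fam_dp, z, tuple(dp) + tuple(e2), e)

    kw = dict(restarts=restarts, seed=seed)
    res_d = mininf(t_d, **kw)
    lift = extend_with_conditional(res_d.argmin, P, dp, tuple(sorted(ds | o1)))
    res_dd = mininf(t_dd, extra_starts=[lift], **kw)
    res_d2 = mininf(t_d, extra_starts=[res_dd.argmin.marginalize(scope_d)], **kw)
    if res_d2.value < res_d.value:
        res_d = res_d2
        lift = extend_with_conditional(res_d.argmin, P, dp, tuple(sorted(ds | o1)))
        res_dd = mininf(t_dd, extra_starts=[lift], **kw)
    res_dp = mininf(t_dp, extra_starts=[lift.marginalize(scope_dp)], **kw)

    eq_gap = abs(res_dd.value - res_d.value)
    dp_slack = res_d.value - res_dp.value
    return DPVerificationReport(
        min_dd=res_dd.value, min_d=res_d.value, min_dp=res_dp.value,
        equality_gap=eq_gap, dp_slack=dp_slack,
        equality_holds=eq_gap <= tol, dp_holds=dp_slack >= -tol, tolerance=tol)
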