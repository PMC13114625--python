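"""Iteration plans: recursive insertion of estimable minInf lower-bound terms.

A plan records how observable variable blocks A_1, ..., A_k are inserted one
data-processing step at a time below an information term that contains hidden
variables. Step j is licensed by a conditional independence
``Z̄_j ⊥ A_j | Ū_j, B̄_j`` and relaxes the preserved marginals of the current
minInf family: the hidden block Ū_j survives only inside the marginal
P(Z̄_j, Ū_j, B̄_j) that carries the next independence, while the companion
marginal P(Z̄_j, C_j) keeps everything previously inserted. The estimable
term contributed by step j is

    min over the step-j family of  I_Q(Z̄_j ; A_j | E, A_[j-1], Ž_[j]),

where the step-j family preserves P(Z̄_j, A_j, B̄_j) and P(Z̄_k, C_k) for
k <= j (hidden variables marginalized in the testable form).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .distributions import _as_names
from .graphs import CausalDAG

__all__ = ["PlanStep", "IterationPlan", "PlanInsert", "PlanValidationReport",
           "PlanConstructionError", "build_plan"]


def _names(x) -> frozenset[str]:
    return frozenset(_as_names(x))


@dataclass(frozen=True)
class PlanStep:
    a: frozenset[str]        # A_j, observables inserted at this step
    bbar: frozenset[str]     # B̄_j, conditioning of the licensing independence
    zcheck: frozenset[str]   # Ž_j, targets moved into conditioning
    zbar: frozenset[str]     # Z̄_j, current target block
    ubar: frozenset[str]     # Ū_j, current hidden block
    c: frozenset[str]        # C_j = {A_{j-1}, B̄_{j-1}, Ž_j}


@dataclass(frozen=True)
class PlanInsert:
    """One requested insertion: the observables A_j and the conditioning B̄_j
    of the licensing independence, with optional role overrides."""
    a: tuple[str, ...]
    bbar: tuple[str, ...]
    zcheck: tuple[str, ...] = ()
    zbar: tuple[str, ...] | None = None   # default: Z̄_{j-1} \ Ž_j
    ubar: tuple[str, ...] | None = None   # default: Ū_{j-1}

    def __init__(self, a, bbar, zcheck=(), zbar=None, ubar=None):
        object.__setattr__(self, "a", _as_names(a))
        object.__setattr__(self, "bbar", _as_names(bbar))
        object.__setattr__(self, "zcheck", _as_names(zcheck))
        object.__setattr__(self, "zbar", None if zbar is None else _as_names(zbar))
        object.__setattr__(self, "ubar", None if ubar is None else _as_names(ubar))


class PlanConstructionError(ValueError):
    pass


@dataclass
class PlanValidationReport:
    valid: bool
    failures: list[str] = field(default_factory=list)

    def first_failure(self) -> str | None:
        return self.failures[0] if self.failures else None


@dataclass
class IterationPlan:
    """The collections A_[k], Z̄_[k], Ž_[k], Ū_[k], B̄_[k], C_[k] plus the
    initial roles E (= B̄_0), Z̄_0 and Ū_0."""

    e: frozenset[str]
    zbar0: frozenset[str]
    ubar0: frozenset[str]
    steps: list[PlanStep]

    def __init__(self, e, zbar0, ubar0, steps: Sequence[PlanStep]):
        self.e = _names(e)
        self.zbar0 = _names(zbar0)
        self.ubar0 = _names(ubar0)
        self.steps = list(steps)

    # -- invariant checking ---------------------------------------------------
    def validate(self, graph: CausalDAG | None = None) -> PlanValidationReport:
        """Check every structural invariant and, if a graph is supplied, the
        licensing independence Z̄_j ⊥ A_j | Ū_j, B̄_j of each step."""
        fails: list[str] = []
        prev_a: frozenset[str] = frozenset()
        prev_bbar = self.e
        prev_zbar, prev_ubar = self.zbar0, self.ubar0
        seen_a: set[str] = set()
        fixed = self.e | self.zbar0 | self.ubar0
        for j, st in enumerate(self.steps, start=1):
            tag = f"step {j}"
            if st.a & (seen_a | fixed):
                fails.append(f"{tag}: A_j overlaps earlier A's or E/Z̄/Ū")
            if not st.zcheck < prev_zbar:
                fails.append(f"{tag}: Ž_j must be a proper subset of Z̄_(j-1)")
            if not st.zbar <= prev_zbar - st.zcheck:
                fails.append(f"{tag}: Z̄_j must be within Z̄_(j-1) \\ Ž_j")
            if j == 1 and st.ubar != self.ubar0:
                fails.append(f"{tag}: Ū_1 must equal Ū_0")
            if not st.ubar <= prev_ubar:
                fails.append(f"{tag}: Ū_j must be within Ū_(j-1)")
            allowed = prev_a | prev_bbar
            if not (st.bbar - st.zcheck) <= allowed:
                fails.append(
                    f"{tag}: B̄_j \\ Ž_j = {sorted(st.bbar - st.zcheck)} not within "
                    f"{{A_(j-1), B̄_(j-1)}} = {sorted(allowed)}")
            expect_c = prev_a | prev_bbar | st.zcheck
            if st.c != expect_c:
                fails.append(f"{tag}: C_j != {{A_(j-1), B̄_(j-1), Ž_j}}")
            if not st.bbar <= st.c:
                fails.append(f"{tag}: B̄_j must be within C_j")
            if graph is not None and not fails:
                if not graph.d_separated(st.zbar, st.a, st.ubar | st.bbar):
                    fails.append(
                        f"{tag}: independence {sorted(st.zbar)} ⊥ {sorted(st.a)} | "
                        f"{sorted(st.ubar | st.bbar)} does not hold in the graph")
            seen_a |= st.a
            prev_a, prev_bbar = st.a, st.bbar
            prev_zbar, prev_ubar = st.zbar, st.ubar
        return PlanValidationReport(valid=not fails, failures=fails)

    # -- derived collections --------------------------------------------------
    def inserted_before(self, j: int) -> frozenset[str]:
        """A_[j-1]: all observables inserted strictly before step j."""
        out: frozenset[str] = frozenset()
        for st in self.steps[:j - 1]:
            out |= st.a
        return out

    def zcheck_upto(self, j: int) -> frozenset[str]:
        """Ž_[j]: all targets moved to conditioning up to and including j."""
        out: frozenset[str] = frozenset()
        for st in self.steps[:j]:
            out |= st.zcheck
        return out

    def objective_conditioning(self, j: int) -> frozenset[str]:
        """Conditioning set {E, A_[j-1], Ž_[j]} of the step-j estimable term."""
        return self.e | self.inserted_before(j) | self.zcheck_upto(j)

    def _companions(self, j: int) -> list[frozenset[str]]:
        return [self.steps[k - 1].zbar | self.steps[k - 1].c
                for k in range(1, j + 1)]

    def preserved_marginals(self, j: int, include_hidden: bool = False
                            ) -> list[frozenset[str]]:
        """Variable subsets whose reference marginals the step-j family
        preserves: {Z̄_j, (Ū_j,) A_j, B̄_j} plus {Z̄_k, C_k} for k <= j,
        with subsets contained in another dropped."""
        st = self.steps[j - 1]
        lead = st.zbar | st.a | st.bbar | (st.ubar if include_hidden else frozenset())
        sets = [lead] + self._companions(j)
        return _collapse(sets)

    def relaxation_marginals(self, j: int, include_hidden: bool = True
                             ) -> list[frozenset[str]]:
        """The relaxed family entering step j: {Z̄_j, (Ū_j,) B̄_j} plus the
        companions {Z̄_k, C_k}, k <= j."""
        st = self.steps[j - 1]
        lead = st.zbar | st.bbar | (st.ubar if include_hidden else frozenset())
        return _collapse([lead] + self._companions(j))

    def relaxation_table(self, include_hidden: bool = True
                         ) -> list[dict[str, list[frozenset[str]]]]:
        """Per step j >= 2: the prior family, its relaxation, and the family
        after inserting A_j (the three columns of a sequential-relaxation
        account of the plan)."""
        rows = []
        for j in range(2, len(self.steps) + 1):
            rows.append({
                "prior": self.preserved_marginals(j - 1, include_hidden),
                "relaxation": self.relaxation_marginals(j, include_hidden),
                "after": self.preserved_marginals(j, include_hidden),
            })
        return rows


def _collapse(sets: Iterable[frozenset[str]]) -> list[frozenset[str]]:
    sets = list(sets)
    out: list[frozenset[str]] = []
    for s in sets:
        if any(s < t for t in sets) or s in out:
            continue
        out.append(s)
    return out


def build_plan(e, zbar0, ubar0,
               inserts: Sequence[PlanInsert | tuple],
               graph: CausalDAG | None = None,
               merge: bool = True) -> IterationPlan:
    """Assemble an :class:`IterationPlan` from an ordered insert sequence.

    Fills C_j = {A_(j-1), B̄_(j-1), Ž_j} and the default role updates
    Z̄_j = Z̄_(j-1) \\ Ž_j, Ū_j = Ū_(j-1). When a step's B̄_j equals the whole
    of {A_(j-1), B̄_(j-1)} (and no role changes), the licensing independencies
    of the two steps contract into one, and the steps are merged. If a graph
    is supplied, each step's licensing independence is required to hold in it.
    """
    e_f, z_f, u_f = _names(e), _names(zbar0), _names(ubar0)
    steps: list[PlanStep] = []
    for raw in inserts:
        ins = raw if isinstance(raw, PlanInsert) else PlanInsert(*raw)
        prev_a = steps[-1].a if steps else frozenset()
        prev_bbar = steps[-1].bbar if steps else e_f
        prev_zbar = steps[-1].zbar if steps else z_f
        prev_ubar = steps[-1].ubar if steps else u_f
        a = _names(ins.a)
        bbar = _names(ins.bbar)
        zcheck = _names(ins.zcheck)
        zbar = _names(ins.zbar) if ins.zbar is not None else prev_zbar - zcheck
        ubar = _names(ins.ubar) if ins.ubar is not None else prev_ubar
        if graph is not None and not graph.d_separated(zbar, a, ubar | bbar):
            raise PlanConstructionError(
                f"insert {len(steps) + 1}: requested independence "
                f"{sorted(zbar)} ⊥ {sorted(a)} | {sorted(ubar | bbar)} "
                f"does not hold in the graph")
        mergeable = (merge and steps and not zcheck
                     and bbar == (prev_a | prev_bbar)
                     and zbar == prev_zbar and ubar == prev_ubar)
        if mergeable:
            last = steps[-1]
            # contraction: Z̄ ⊥ A_(j-1) | ŪB̄_(j-1) and Z̄ ⊥ A_j | ŪA_(j-1)B̄_(j-1)
            # jointly give Z̄ ⊥ {A_(j-1), A_j} | ŪB̄_(j-1)
            steps[-1] = PlanStep(a=last.a | a, bbar=last.bbar, zcheck=last.zcheck,
                                 zbar=last.zbar, ubar=last.ubar, c=last.c)
            continue
        c = prev_a | prev_bbar | zcheck
        steps.append(PlanStep(a=a, bbar=bbar, zcheck=zcheck, zbar=zbar,
                              ubar=ubar, c=c))
    plan = IterationPlan(e_f, z_f, u_f, steps)
    report = plan.validate(graph)
    if not report.valid:
        raise PlanConstructionError(report.first_failure())
    return plan
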