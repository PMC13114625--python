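"""Canonical causal scenarios, discrete-SCM sampling, and violating fixtures.

The figure registry encodes the hidden-variable causal structures used
throughout the package as explicit DAGs, each validated against a checklist
of the conditional (in)dependencies that define the scenario — the
checklist, not any drawing, is the contract. ``sample_scm`` turns a DAG plus
a mechanism specification into the *exact* joint distribution (a product of
conditional probability tables; no sampling noise), including hidden nodes,
from which the observable marginal scenario is derived.

Constructed violating distributions pair a distribution with the inequality
it defeats; they are deterministic closed-form tables, byte-identical across
runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .distributions import DiscreteJointDistribution, VariableSet, _as_names
from .graphs import CausalDAG
from .inequalities import (ChainPartition, Group, GroupCollection, ICScenario,
                           InequalityResult, InstrumentalSpec,
                           eval_combined, eval_gd1, eval_ic,
                           eval_mininf_instrumental,
                           eval_standard_instrumental,
                           eval_unique_instrumental, plan_from_independencies)
from .optimize import extend_with_cpt

__all__ = [
    "MechanismSpec", "FigureScenario", "figure_structure", "figure_names",
    "sample_scm", "ViolationCase", "violating_distribution", "violation_names",
    "empirical_distribution", "bootstrap_slack",
    "FulfillmentCase", "fulfillment_cases",
]


# ---------------------------------------------------------------------------
# discrete structural causal models
# ---------------------------------------------------------------------------

@dataclass
class MechanismSpec:
    """Per-node conditional-table parameterization for a discrete SCM.

    ``mechanisms`` maps a node to one of: ``"random"`` (Dirichlet rows),
    ``("random", concentration)``, ``"copy"`` (first parent, mod card),
    ``"xor"`` (parent sum mod card), ``"and"`` / ``"or"`` (binary),
    ``("noisy-copy", flip_rate)``, ``"uniform"``, or an explicit ndarray of
    shape (*parent cards, card). Unlisted nodes default to ``"random"``.
    """

    mechanisms: Mapping[str, object] = field(default_factory=dict)
    cardinalities: Mapping[str, int] = field(default_factory=dict)
    seed: int = 0
    default_concentration: float = 1.0

    def card(self, node: str) -> int:
        return int(self.cardinalities.get(node, 2))


def _mech_cpt(kind, parent_cards: Sequence[int], card: int,
              rng: np.random.Generator, conc: float) -> np.ndarray:
    n_rows = int(np.prod(parent_cards)) if parent_cards else 1
    if isinstance(kind, np.ndarray):
        return np.asarray(kind, dtype=float)
    if isinstance(kind, tuple):
        kind, param = kind
    else:
        param = None
    rows = np.zeros((n_rows, card))
    if kind == "random":
        rows = rng.dirichlet(np.full(card, param if param is not None else conc),
                             size=n_rows)
    elif kind == "uniform":
        rows[:] = 1.0 / card
    else:
        for r, combo in enumerate(np.ndindex(*parent_cards) if parent_cards
                                  else [()]):
            if kind == "copy":
                val = (combo[0] if combo else 0) % card
            elif kind == "xor":
                val = sum(combo) % card
            elif kind == "and":
                val = int(all(combo)) % card
            elif kind == "or":
                val = int(any(combo)) % card
            elif kind == "noisy-copy":
                val = (combo[0] if combo else 0) % card
                flip = float(param if param is not None else 0.1)
                rows[r] = flip / (card - 1) if card > 1 else 1.0
                rows[r, val] = 1.0 - flip
                continue
            else:
                raise ValueError(f"unknown mechanism kind {kind!r}")
            rows[r, val] = 1.0
    return rows.reshape(tuple(parent_cards) + (card,))


def sample_scm(G: CausalDAG, mech: MechanismSpec) -> DiscreteJointDistribution:
    """Exact joint distribution of the SCM (hidden nodes included).

    Nodes are processed in topological order; each node's conditional table
    is multiplied onto the accumulating joint. The observable marginal
    scenario is obtained by marginalizing the hidden nodes afterwards.
    """
    rng = np.random.default_rng(mech.seed)
    order = G.topological_order()
    joint: DiscreteJointDistribution | None = None
    for node in order:
        parents = [p for p in (joint.variables.names if joint else ())
                   if p in set(G.parents(node))]
        if set(G.parents(node)) - set(parents):
            raise ValueError(f"node {node} has parents outside the prefix")
        card = mech.card(node)
        kind = mech.mechanisms.get(node, "random")
        cpt = _mech_cpt(kind, [mech.card(p) for p in parents], card, rng,
                        mech.default_concentration)
        if joint is None:
            base = DiscreteJointDistribution(VariableSet([], []),
                                             np.array(1.0), _validate=False)
            joint = extend_with_cpt(base, node, card, [], cpt)
        else:
            joint = extend_with_cpt(joint, node, card, parents, cpt)
    assert joint is not None
    return joint


# ---------------------------------------------------------------------------
# figure registry
# ---------------------------------------------------------------------------

@dataclass
class FigureScenario:
    name: str
    dag: CausalDAG
    roles: dict
    independencies: list[tuple[tuple, tuple, frozenset]]
    dependencies: list[tuple[tuple, tuple, frozenset]]
    description: str = ""

    def checklist_ok(self) -> bool:
        for a, b, s in self.independencies:
            if not self.dag.d_separated(a, b, s):
                return False
        for a, b, s in self.dependencies:
            if self.dag.d_separated(a, b, s):
                return False
        return True


def _triple(a, b, s):
    return (_as_names(a), _as_names(b), frozenset(_as_names(s)))


def _registry() -> dict[str, FigureScenario]:
    reg: dict[str, FigureScenario] = {}

    def add(name, nodes, hidden, edges, roles, indep, dep, desc=""):
        reg[name] = FigureScenario(
            name, CausalDAG(nodes, edges, hidden=hidden), roles,
            [_triple(*t) for t in indep], [_triple(*t) for t in dep], desc)

    add("fig1A", ["Z", "X", "Y", "W", "U"], ["U"],
        [("W", "Z"), ("W", "Y"), ("Z", "X"), ("U", "X"), ("U", "Y"),
         ("X", "Y")],
        {"z": ("Z",), "x": ("X",), "y": ("Y",), "b0": ("W",), "u": ("U",)},
        indep=[("Z", "U", ("W",)), ("Z", "Y", ("U", "X", "W"))],
        dep=[("Z", "Y", ()), ("Z", "Y", ("X",)), ("Z", "Y", ("U", "X"))],
        desc="standard instrumental scenario; W a noncollider conditioner")

    add("fig1B", ["Z", "X", "Y", "W", "U"], ["U"],
        [("Z", "W"), ("Y", "W"), ("U", "X"), ("U", "Y"), ("Z", "X"),
         ("X", "Y")],
        {"z": ("Z",), "x": ("X",), "y": ("Y",), "b0": ("W",),
         "b1": (), "b2": ("W",), "u": ("U",)},
        indep=[("Z", "U", ()), ("Z", "Y", ("U", "X"))],
        dep=[("Z", "Y", ("U", "X", "W")), ("Z", "U", ("W",))],
        desc="W a collider between Z and Y; unique-information scenario")

    add("fig1C", ["Z", "X", "Y", "W1", "W2", "U"], ["U"],
        [("W1", "Z"), ("W2", "Z"), ("W1", "U"), ("W2", "U"), ("U", "X"),
         ("U", "Y"), ("Z", "X"), ("X", "Y")],
        {"z": ("Z",), "x": ("X",), "y": ("Y",), "b0": ("W1", "W2"),
         "b1": (), "b2": ("W1", "W2"), "u": ("U",)},
        indep=[("Z", "U", ("W1", "W2")), ("Z", "Y", ("U", "X"))],
        dep=[("W1", "U", ("W2",)), ("W2", "U", ("W1",)), ("W1", "U", ()),
             ("Z", "U", ("W1",)), ("Z", "U", ())],
        desc="no instrumental set containing W1 or W2 exists; unique "
             "information with bivariate reference adds power")

    fig2a_edges = [("W1", "Z"), ("W1", "U"), ("W1", "Y1"), ("W1", "Y2"),
                   ("U", "X"), ("U", "Y1"), ("Z", "X"), ("X", "Y1"),
                   ("Z", "W2"), ("Y2", "W2"), ("W2", "Y1")]
    add("fig2A", ["Z", "X", "Y1", "Y2", "W1", "W2", "U"], ["U"], fig2a_edges,
        {"z": ("Z",), "x": ("X",), "y": ("Y1", "Y2"), "b0": ("W1", "W2"),
         "b1": ("W1",), "b2": ("W2",), "y1": ("Y1",), "y2": ("Y2",),
         "ybar": ("Y1",), "u": ("U",)},
        indep=[("Z", "U", ("W1", "W2")), ("Z", "Y1", ("U", "X", "W1", "W2")),
               ("Z", "Y2", ("U", "X", "W1")),
               (("Z", "W2"), ("U",), ("W1",))],
        dep=[("Z", "Y2", ("U", "X", "W1", "W2")),
             ("Z", "Y2", ("U", "X", "W1", "Y1")),
             ("Z", "Y1", ("U", "X", "W1")), ("W1", "U", ())],
        desc="W2 a noncollider toward Y1 but a collider toward Y2, with Y1 "
             "a descendant of W2: conditional mutual information and unique "
             "information steps must be combined")

    add("fig2B", ["Z", "X", "Y1", "Y2", "W1", "W2", "U"], ["U"],
        [e for e in fig2a_edges if e != ("W2", "Y1")],
        {"z": ("Z",), "x": ("X",), "y": ("Y1", "Y2"), "b0": ("W1", "W2"),
         "b1": ("W1",), "b2": ("W2",), "y1": ("Y1",), "y2": ("Y2",),
         "ybar": (), "u": ("U",)},
        indep=[("Z", "U", ("W1", "W2")), ("Z", "Y1", ("U", "X", "W1", "W2")),
               ("Z", "Y1", ("U", "X", "W1")),
               ("Z", "Y2", ("U", "X", "W1", "Y1"))],
        dep=[("Z", "Y2", ("U", "X", "W1", "Y1", "W2")), ("W1", "U", ())],
        desc="as fig2A but Y1 not a descendant of W2, so Y1 may stay in "
             "the unique-information conditioning (Ȳ = ∅)")

    # variants named in the text: the same inequalities hold without W1-U or
    # without W1-Y1
    add("fig2A-noW1U", ["Z", "X", "Y1", "Y2", "W1", "W2", "U"], ["U"],
        [e for e in fig2a_edges if e != ("W1", "U")],
        reg["fig2A"].roles,
        indep=[("Z", "U", ("W1", "W2")), ("Z", "Y1", ("U", "X", "W1", "W2")),
               ("Z", "Y2", ("U", "X", "W1"))],
        dep=[("Z", "Y2", ("U", "X", "W1", "W2"))],
        desc="fig2A without the W1->U edge")
    add("fig2A-noW1Y1", ["Z", "X", "Y1", "Y2", "W1", "W2", "U"], ["U"],
        [e for e in fig2a_edges if e != ("W1", "Y1")],
        reg["fig2A"].roles,
        indep=[("Z", "U", ("W1", "W2")), ("Z", "Y1", ("U", "X", "W1", "W2")),
               ("Z", "Y2", ("U", "X", "W1"))],
        dep=[("Z", "Y2", ("U", "X", "W1", "W2"))],
        desc="fig2A without the W1->Y1 edge")

    add("fig2C", ["Z", "X", "Y1", "Y2", "Y3", "W2", "W3", "U"], ["U"],
        [("Z", "X"), ("Z", "W2"), ("Z", "W3"), ("U", "X"), ("U", "Y1"),
         ("W2", "Y1"), ("X", "Y1"), ("Y2", "W2"), ("Y3", "W3")],
        {"z": ("Z",), "x": ("X",), "y": ("Y1", "Y2", "Y3"),
         "b0": ("W2", "W3"), "u": ("U",),
         "plan_inserts": ((("Y1",), ("X", "W2", "W3")),
                          (("Y2",), ("X", "W3")),
                          (("Y3",), ("X", "Y2")))},
        indep=[("Z", "U", ("W2", "W3")),
               ("Z", "Y1", ("U", "X", "W2", "W3")),
               ("Z", "Y2", ("U", "X", "W3")),
               ("Z", "Y3", ("U", "X", "Y2"))],
        dep=[("Z", "Y2", ("U", "X", "W3", "W2")),
             ("Z", "Y2", ("U", "X", "W3", "Y1")),
             ("Z", "Y3", ("U", "X", "Y2", "W3"))],
        desc="three-step scenario: a conditional-mutual-information step, a "
             "unique-information step, and a general minInf step")

    add("fig3A", ["Y", "Z", "V1", "V2", "U1", "U2"], ["U1", "U2"],
        [("Z", "Y"), ("Z", "V1"), ("Z", "V2"), ("U1", "V1"), ("U1", "Y"),
         ("U2", "V2"), ("U2", "Y")],
        {"y": ("Y",), "z": ("Z",),
         "groups": ((("U1",), ("V1",)), (("U2",), ("V2",)))},
        indep=[("U1", "U2", ("Z",)), ("Y", "V1", ("Z", "U1")),
               ("Y", "V2", ("Z", "U2"))],
        dep=[("Y", "V1", ("Z",))],
        desc="common-ancestors structure after conditioning on Z; "
             "groups-decomposition (GD1) scenario")

    add("fig3B", ["X1", "X2", "M", "Y1", "Y2", "U"], ["U"],
        [("X1", "M"), ("X2", "M"), ("U", "M"), ("M", "Y1"), ("M", "Y2"),
         ("U", "Y1"), ("U", "Y2")],
        {"x": ("X1", "X2"), "m": ("M",), "y": ("Y1", "Y2"), "u": ("U",)},
        indep=[(("X1", "X2"), ("U",), ()), ("X1", "Y1", ("U", "M")),
               ("X2", "Y2", ("U", "M", "X1"))],
        dep=[("X1", "Y1", ("M",))],
        desc="information-causality scenario: Y1, Y2 mutually exclusively "
             "observable")
    return reg


_REGISTRY = _registry()


def figure_names() -> list[str]:
    return sorted(_REGISTRY)


def figure_structure(name: str) -> FigureScenario:
    """The registered DAG, role assignment, and independence checklist."""
    if name not in _REGISTRY:
        raise KeyError(f"unknown scenario {name!r}; known: {figure_names()}")
    return _REGISTRY[name]


# ---------------------------------------------------------------------------
# causal-fulfillment cases: (figure, inequality) pairs imposed by structure
# ---------------------------------------------------------------------------

@dataclass
class FulfillmentCase:
    """A causally imposed inequality: slack must be >= -epsilon for every
    distribution generated from the scenario's structure."""
    name: str
    figure: str
    epsilon: float
    _eval: Callable[[DiscreteJointDistribution], InequalityResult]

    def sample(self, seed: int) -> DiscreteJointDistribution:
        fig = figure_structure(self.figure)
        return sample_scm(fig.dag, MechanismSpec(seed=seed))

    def evaluate(self, joint: DiscreteJointDistribution) -> InequalityResult:
        return self._eval(joint)


def _obs(joint: DiscreteJointDistribution, fig: FigureScenario
         ) -> DiscreteJointDistribution:
    return joint.marginalize([n for n in joint.variables.names
                              if n not in fig.dag.hidden])


def fulfillment_cases() -> list[FulfillmentCase]:
    cases: list[FulfillmentCase] = []

    def spec_of(fig: FigureScenario) -> InstrumentalSpec:
        roles = {k: v for k, v in fig.roles.items() if k != "plan_inserts"
                 and k != "groups" and k != "m"}
        return InstrumentalSpec(**roles)

    def closed(figname, evalf):
        return FulfillmentCase(f"{figname}", figname, 1e-9, evalf)

    fig = figure_structure("fig1A")
    cases.append(FulfillmentCase(
        "fig1A/standard", "fig1A", 1e-9,
        lambda j, fig=fig: eval_standard_instrumental(_obs(j, fig), spec_of(fig))))

    fig = figure_structure("fig1B")
    cases.append(FulfillmentCase(
        "fig1B/unique", "fig1B", 1e-5,
        lambda j, fig=fig: eval_unique_instrumental(_obs(j, fig), spec_of(fig))))

    fig = figure_structure("fig1C")
    cases.append(FulfillmentCase(
        "fig1C/unique-bivariate-reference", "fig1C", 1e-5,
        lambda j, fig=fig: eval_unique_instrumental(_obs(j, fig), spec_of(fig))))

    for name in ("fig2A", "fig2B"):
        fig = figure_structure(name)
        cases.append(FulfillmentCase(
            f"{name}/combined", name, 1e-5,
            lambda j, fig=fig: eval_combined(_obs(j, fig), spec_of(fig))))

    fig = figure_structure("fig2C")

    def _eval_fig2c(joint, fig=fig):
        spec = spec_of(fig)
        partition = ChainPartition([spec.z])
        plan = plan_from_independencies(fig.dag, spec,
                                        fig.roles["plan_inserts"])
        return eval_mininf_instrumental(_obs(joint, fig), spec, partition,
                                        [plan], restarts=4)

    cases.append(FulfillmentCase("fig2C/mininf-three-step", "fig2C", 1e-5,
                                 _eval_fig2c))

    fig = figure_structure("fig3A")

    def _eval_fig3a(joint, fig=fig):
        gc = GroupCollection(fig.roles["y"], fig.roles["z"],
                             [Group(members, proxy=proxy)
                              for members, proxy in fig.roles["groups"]],
                             hidden=fig.dag.hidden)
        return eval_gd1(joint, gc, testable_only=True)

    cases.append(FulfillmentCase("fig3A/gd1", "fig3A", 1e-9, _eval_fig3a))

    fig = figure_structure("fig3B")

    def _eval_fig3b(joint, fig=fig):
        scn = ICScenario.from_joint(_obs(joint, fig), fig.roles["x"],
                                    fig.roles["m"], fig.roles["y"])
        return eval_ic(scn)

    cases.append(FulfillmentCase("fig3B/ic", "fig3B", 1e-9, _eval_fig3b))
    return cases


# ---------------------------------------------------------------------------
# constructed violating distributions
# ---------------------------------------------------------------------------

@dataclass
class ViolationCase:
    """A frozen distribution paired with the inequality test it defeats."""
    name: str
    dist: DiscreteJointDistribution
    kind: str
    spec: InstrumentalSpec
    evaluate: Callable[[], InequalityResult]
    description: str = ""


def _relay_table(with_w: bool) -> DiscreteJointDistribution:
    # Z = (Z1, Z2) uniform; the one-bit channel X relays only Z1, Y reads Z2
    names = ["Z1", "Z2", "X", "Y"] + (["W"] if with_w else [])
    vs = VariableSet(names, [2] * len(names))
    probs = np.zeros(tuple(vs.cardinalities))
    for z1 in range(2):
        for z2 in range(2):
            if with_w:
                for w in range(2):
                    probs[z1, z2, z1, z2, w] = 1 / 8
            else:
                probs[z1, z2, z1, z2] = 1 / 4
    return DiscreteJointDistribution(vs, probs)


def _breaker_table() -> DiscreteJointDistribution:
    # fig2C observable structure with an added Z->Y3 edge: Z has four states
    # (two bits), X transmits the high bit, Y3 copies the low bit; the third
    # minInf term then certifies one full bit that the X channel cannot carry
    names = ["Z", "X", "Y1", "Y2", "Y3", "W2", "W3"]
    vs = VariableSet(names, [4, 2, 2, 2, 2, 1, 1])
    probs = np.zeros(tuple(vs.cardinalities))
    for z in range(4):
        for y2 in range(2):
            probs[z, z // 2, z // 2, y2, z % 2, 0, 0] = 1 / 8
    return DiscreteJointDistribution(vs, probs)


def violation_names() -> list[str]:
    return ["two-bit-relay", "two-bit-relay-W", "fig2C-breaker"]


def violating_distribution(name: str) -> ViolationCase:
    """A constructed counterexample and the inequality it violates
    (evaluated in testable mode)."""
    if name == "two-bit-relay":
        dist = _relay_table(with_w=False)
        spec = InstrumentalSpec(z=("Z1", "Z2"), x=("X",), y=("Y",))
        return ViolationCase(
            name, dist, "standard", spec,
            lambda: eval_standard_instrumental(dist, spec),
            "two uniform instrument bits relayed through a one-bit channel; "
            "slack is exactly -1 bit")
    if name == "two-bit-relay-W":
        dist = _relay_table(with_w=True)
        spec = InstrumentalSpec(z=("Z1", "Z2"), x=("X",), y=("Y",),
                                b0=("W",), b1=(), b2=("W",))
        return ViolationCase(
            name, dist, "unique", spec,
            lambda: eval_unique_instrumental(dist, spec),
            "the relay with an independent W in the unique-information "
            "reference; the preserved marginals pin the violation")
    if name == "fig2C-breaker":
        dist = _breaker_table()
        fig = figure_structure("fig2C")
        spec = InstrumentalSpec(z=("Z",), x=("X",), y=("Y1", "Y2", "Y3"),
                                b0=("W2", "W3"), u=("U",))
        partition = ChainPartition([spec.z])
        plan = plan_from_independencies(fig.dag, spec,
                                        fig.roles["plan_inserts"])
        return ViolationCase(
            name, dist, "mininf", spec,
            lambda: eval_mininf_instrumental(dist, spec, partition, [plan],
                                             restarts=4),
            "fig2C with a direct Z->Y3 copy of the bit the X channel drops; "
            "the three-term minInf bound rejects while the Y1-only standard "
            "bound does not")
    raise KeyError(f"unknown violation fixture {name!r}")


# ---------------------------------------------------------------------------
# empirical plug-in path
# ---------------------------------------------------------------------------

def fixture_path(filename: str):
    """Path of a shipped fixture file (scenario DAG JSON or violating
    distribution table); the same files `mininf fixtures emit` regenerates."""
    from importlib.resources import files

    path = files("mininf").joinpath("fixtures", filename)
    if not path.is_file():
        raise KeyError(f"no shipped fixture named {filename!r}")
    return path


def empirical_distribution(counts, variables: VariableSet | None = None
                           ) -> DiscreteJointDistribution:
    """Plug-in distribution from a nonnegative integer count table.

    Zero-count outcomes get mass exactly 0 — no smoothing or bias correction
    is applied. Accepts a dense ndarray with an explicit VariableSet, or a
    DataFrame with one column per variable and a final ``n`` column.
    """
    if isinstance(counts, pd.DataFrame):
        arr_vs = _counts_frame_to_array(counts)
        counts, variables = arr_vs
    counts = np.asarray(counts, dtype=float)
    if variables is None:
        raise ValueError("variables required for array input")
    if np.any(counts < 0) or np.any(counts != np.round(counts)):
        raise ValueError("counts must be nonnegative integers")
    total = counts.sum()
    if total == 0:
        raise ValueError("all-zero count table")
    return DiscreteJointDistribution(variables, counts / total)


def _counts_frame_to_array(df: pd.DataFrame):
    if df.columns[-1] != "n":
        raise ValueError("count frame needs a final 'n' column")
    var_cols = list(df.columns[:-1])
    levels = {c: sorted(df[c].astype(str).unique()) for c in var_cols}
    vs = VariableSet(var_cols, [len(levels[c]) for c in var_cols])
    arr = np.zeros(tuple(vs.cardinalities))
    for row in df.itertuples(index=False):
        idx = tuple(levels[c].index(str(v)) for c, v in zip(var_cols, row))
        arr[idx] += float(row[-1])
    return arr, vs


def bootstrap_slack(counts: np.ndarray, variables: VariableSet,
                    evaluate: Callable[[DiscreteJointDistribution],
                                       InequalityResult],
                    n_boot: int = 200, seed: int = 0,
                    alpha: float = 0.05) -> tuple[np.ndarray, tuple[float, float]]:
    """Heuristic nonparametric bootstrap of an inequality slack.

    Resamples the count table multinomially, evaluates the slack on each
    plug-in distribution, and returns the slacks with a percentile interval.
    This is a rough finite-sample diagnostic only: no estimation theory
    backs the plug-in information measures.
    """
    counts = np.asarray(counts, dtype=float)
    n = int(counts.sum())
    p = (counts / n).ravel()
    rng = np.random.default_rng(seed)
    slacks = np.empty(n_boot)
    for b in range(n_boot):
        resampled = rng.multinomial(n, p).reshape(counts.shape)
        dist = empirical_distribution(resampled, variables)
        slacks[b] = evaluate(dist).slack
    lo, hi = np.quantile(slacks, [alpha / 2, 1 - alpha / 2])
    return slacks, (float(lo), float(hi))
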