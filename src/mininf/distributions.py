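"""Exact discrete joint distributions and Shannon information measures.

All entropic quantities are computed in bits (base-2 logarithms) directly on
dense probability tables, with the standard convention ``0 * log 0 = 0``.
Distributions are exact objects: no estimation or smoothing is performed here
(an empirical plug-in path lives in :mod:`mininf.scenarios`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy

__all__ = [
    "VariableSet",
    "DiscreteJointDistribution",
    "BasicInequalityRecord",
    "read_table",
    "write_table",
]

#: absolute tolerance on the total probability mass
MASS_TOL = 1e-12
#: largest dense table this module will represent
MAX_CELLS = 10**6
#: |I| below this is treated as exactly zero (float round-off)
CMI_CLIP = 1e-12
#: default decision threshold for conditional-independence tests, in bits
INDEP_TOL = 1e-9

_LOG2 = np.log(2.0)


def _as_names(spec: "VariableSet | Iterable[str] | str | None") -> tuple[str, ...]:
    """Coerce a role-set argument (VariableSet, name iterable, single name, None)."""
    if spec is None:
        return ()
    if isinstance(spec, VariableSet):
        return spec.names
    if isinstance(spec, str):
        return (spec,)
    return tuple(spec)


@dataclass(frozen=True)
class VariableSet:
    """An ordered collection of distinct, finite-cardinality variables.

    Set operations are label-based and order-insensitive; the stored order is
    only used to give tables and files a deterministic layout.
    """

    names: tuple[str, ...]
    cardinalities: tuple[int, ...]

    def __init__(self, names: Iterable[str], cardinalities: Iterable[int]):
        names = tuple(names)
        cards = tuple(int(c) for c in cardinalities)
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate variable labels in {names}")
        if len(names) != len(cards):
            raise ValueError("names and cardinalities differ in length")
        if any(c < 1 for c in cards):
            raise ValueError("every cardinality must be >= 1")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "cardinalities", cards)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def cardinality(self, name: str) -> int:
        return self.cardinalities[self.names.index(name)]

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.cardinalities, dtype=object)) if self.names else 1

    # -- label-based set algebra --------------------------------------------
    def subset(self, names: Iterable[str]) -> "VariableSet":
        """The sub-collection with the given labels, in this set's order."""
        wanted = set(_as_names(names))
        unknown = wanted - set(self.names)
        if unknown:
            raise KeyError(f"unknown variable label(s): {sorted(unknown)}")
        keep = [n for n in self.names if n in wanted]
        return VariableSet(keep, [self.cardinality(n) for n in keep])

    def union(self, other: "VariableSet | Iterable[str]") -> "VariableSet":
        if isinstance(other, VariableSet):
            extra = [(n, c) for n, c in zip(other.names, other.cardinalities)
                     if n not in self.names]
            return VariableSet(self.names + tuple(n for n, _ in extra),
                               self.cardinalities + tuple(c for _, c in extra))
        raise TypeError("union with bare names needs cardinalities; pass a VariableSet")

    def difference(self, other: Iterable[str]) -> "VariableSet":
        drop = set(_as_names(other))
        keep = [n for n in self.names if n not in drop]
        return VariableSet(keep, [self.cardinality(n) for n in keep])

    def intersection(self, other: Iterable[str]) -> "VariableSet":
        return self.subset(set(self.names) & set(_as_names(other)))

    def issubset(self, other: "VariableSet | Iterable[str]") -> bool:
        return set(self.names) <= set(_as_names(other))

    def isdisjoint(self, other: Iterable[str]) -> bool:
        return not (set(self.names) & set(_as_names(other)))


def _check_disjoint(**role_sets: tuple[str, ...]) -> None:
    items = list(role_sets.items())
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            overlap = set(items[i][1]) & set(items[j][1])
            if overlap:
                raise ValueError(
                    f"role sets {items[i][0]} and {items[j][0]} overlap on {sorted(overlap)}"
                )


class DiscreteJointDistribution:
    """A normalized probability table over a :class:`VariableSet`.

    The table is stored densely as an ``ndarray`` whose axes follow
    ``variables.names``. All information measures defined on the distribution
    (entropies, conditional mutual informations, the basic Shannon-cone
    inequalities) are exact up to float arithmetic.
    """

    def __init__(self, variables: VariableSet, probs: np.ndarray, *,
                 _validate: bool = True):
        probs = np.asarray(probs, dtype=float)
        if variables.n_cells > MAX_CELLS:
            raise ValueError(
                f"table with {variables.n_cells} cells exceeds the dense limit {MAX_CELLS}"
            )
        if probs.shape != tuple(variables.cardinalities):
            probs = probs.reshape(tuple(variables.cardinalities))
        if _validate:
            if np.any(probs < -MASS_TOL):
                raise ValueError("negative probability mass in table")
            total = float(probs.sum())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"probability masses sum to {total}, not 1")
            probs = np.clip(probs, 0.0, None)
            probs = probs / probs.sum()
        self.variables = variables
        self.probs = probs

    # -- constructors --------------------------------------------------------
    @classmethod
    def from_mapping(cls, variables: VariableSet,
                     table: Mapping[tuple, float]) -> "DiscreteJointDistribution":
        probs = np.zeros(tuple(variables.cardinalities))
        for outcome, p in table.items():
            probs[tuple(outcome)] = p
        return cls(variables, probs)

    @classmethod
    def uniform(cls, variables: VariableSet) -> "DiscreteJointDistribution":
        n = variables.n_cells
        return cls(variables, np.full(tuple(variables.cardinalities), 1.0 / n))

    @classmethod
    def random(cls, variables: VariableSet, rng: np.random.Generator,
               concentration: float = 1.0) -> "DiscreteJointDistribution":
        """A Dirichlet(concentration) draw on the joint simplex."""
        p = rng.dirichlet(np.full(variables.n_cells, concentration))
        return cls(variables, p.reshape(tuple(variables.cardinalities)))

    # -- basic structure -----------------------------------------------------
    def _axes(self, names: Sequence[str]) -> tuple[int, ...]:
        return tuple(self.variables.names.index(n) for n in names)

    def marginalize(self, keep: "VariableSet | Iterable[str]") -> "DiscreteJointDistribution":
        """Sum out every variable not in ``keep`` (order follows this table)."""
        keep_vs = self.variables.subset(_as_names(keep))
        drop_axes = tuple(i for i, n in enumerate(self.variables.names)
                          if n not in keep_vs.names)
        probs = self.probs.sum(axis=drop_axes) if drop_axes else self.probs
        return DiscreteJointDistribution(keep_vs, probs, _validate=False)

    def _marginal_array(self, names: Sequence[str]) -> np.ndarray:
        drop = tuple(i for i, n in enumerate(self.variables.names) if n not in names)
        return self.probs.sum(axis=drop) if drop else self.probs

    # -- information measures ------------------------------------------------
    def entropy(self, of: "VariableSet | Iterable[str] | None" = None) -> float:
        """Joint Shannon entropy H(of) in bits (H(∅) = 0)."""
        names = _as_names(of) if of is not None else self.variables.names
        self.variables.subset(names)  # validates labels
        if not names:
            return 0.0
        p = self._marginal_array([n for n in self.variables.names if n in set(names)])
        return float(-xlogy(p, p).sum() / _LOG2)

    def conditional_entropy(self, a: "VariableSet | Iterable[str]",
                            c: "VariableSet | Iterable[str] | None" = None) -> float:
        """H(A | C) = H(A,C) - H(C), in bits."""
        a_n, c_n = _as_names(a), _as_names(c)
        _check_disjoint(A=a_n, C=c_n)
        h = self.entropy(set(a_n) | set(c_n)) - self.entropy(c_n)
        return max(h, 0.0) if h > -1e-9 else h

    def conditional_mutual_information(
            self, a: "VariableSet | Iterable[str]", b: "VariableSet | Iterable[str]",
            c: "VariableSet | Iterable[str] | None" = None) -> float:
        """I(A ; B | C) = H(A,C) + H(B,C) - H(A,B,C) - H(C), in bits."""
        a_n, b_n, c_n = _as_names(a), _as_names(b), _as_names(c)
        _check_disjoint(A=a_n, B=b_n, C=c_n)
        a_s, b_s, c_s = set(a_n), set(b_n), set(c_n)
        value = (self.entropy(a_s | c_s) + self.entropy(b_s | c_s)
                 - self.entropy(a_s | b_s | c_s) - self.entropy(c_s))
        if abs(value) <= CMI_CLIP:
            return 0.0
        return value

    def mutual_information(self, a, b) -> float:
        return self.conditional_mutual_information(a, b, ())

    def is_conditionally_independent(self, a, b, c=(), tol: float = INDEP_TOL) -> bool:
        """True iff I(A;B|C) <= tol bits."""
        if tol <= 0:
            raise ValueError("tol must be positive")
        return self.conditional_mutual_information(a, b, c) <= tol

    # -- Shannon-cone validity ----------------------------------------------
    def check_basic_inequalities(self) -> list["BasicInequalityRecord"]:
        """Evaluate every basic (polymatroid) inequality over variable subsets.

        Emits one record per instance of: H(∅)=0; monotonicity H(T) >= H(S)
        for S ⊆ T with |T \\ S| = 1; and submodularity
        I(S;T|S∩T) >= 0 for incomparable S, T. Any valid distribution has all
        slacks >= 0 up to float noise.
        """
        names = self.variables.names
        if len(names) > 6:
            raise ValueError("basic-inequality enumeration limited to 6 variables")
        ent: dict[frozenset, float] = {}
        for r in range(len(names) + 1):
            for combo in itertools.combinations(names, r):
                ent[frozenset(combo)] = self.entropy(combo)
        records = [BasicInequalityRecord("H(empty)=0", abs(ent[frozenset()]))]
        full = frozenset(names)
        for s_f, h_s in ent.items():
            # monotonicity, one added variable at a time (generates the rest)
            for v in full - s_f:
                t_f = s_f | {v}
                records.append(BasicInequalityRecord(
                    f"H({_fmt(t_f)})>=H({_fmt(s_f)})", ent[t_f] - h_s))
        subsets = list(ent)
        for i, s_f in enumerate(subsets):
            for t_f in subsets[i + 1:]:
                if s_f <= t_f or t_f <= s_f or not s_f or not t_f:
                    continue
                inter = s_f & t_f
                slack = ent[s_f] + ent[t_f] - ent[s_f | t_f] - ent[inter]
                records.append(BasicInequalityRecord(
                    f"I({_fmt(s_f)};{_fmt(t_f)}|{_fmt(inter)})>=0", slack))
        return records

    # -- misc -----------------------------------------------------------------
    def permuted(self, order: Sequence[str]) -> "DiscreteJointDistribution":
        """Same distribution with axes reordered to ``order``."""
        order = tuple(order)
        if set(order) != set(self.variables.names):
            raise ValueError("order must be a permutation of the variable labels")
        axes = self._axes(order)
        vs = VariableSet(order, [self.variables.cardinality(n) for n in order])
        return DiscreteJointDistribution(vs, np.transpose(self.probs, axes),
                                         _validate=False)

    def allclose(self, other: "DiscreteJointDistribution", atol: float = 1e-10) -> bool:
        if set(other.variables.names) != set(self.variables.names):
            return False
        return np.allclose(self.probs, other.permuted(self.variables.names).probs,
                           atol=atol)

    def __repr__(self) -> str:
        return (f"DiscreteJointDistribution({list(self.variables.names)}, "
                f"cards={list(self.variables.cardinalities)})")


def _fmt(s: frozenset) -> str:
    return ",".join(sorted(s)) if s else "empty"


@dataclass(frozen=True)
class BasicInequalityRecord:
    inequality: str
    slack: float


# ---------------------------------------------------------------------------
# Tabular probability files: one column per variable, final column `p`
# (probabilities) or `n` (nonnegative integer counts, plug-in normalized).
# ---------------------------------------------------------------------------

def read_table(path, sep: str = ",") -> DiscreteJointDistribution:
    """Read a delimited probability (``p``) or count (``n``) table.

    State labels are arbitrary strings; they are mapped to indices in sorted
    order so the representation is deterministic. A probability column must
    sum to 1 within 1e-6; a count column must hold nonnegative integers.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.columns[-1] not in ("p", "n"):
        raise ValueError("last column must be 'p' (probability) or 'n' (counts)")
    kind = df.columns[-1]
    var_cols = list(df.columns[:-1])
    if not var_cols:
        raise ValueError("table has no variable columns")
    weights = pd.to_numeric(df[kind]).to_numpy(dtype=float)
    if kind == "p":
        total = weights.sum()
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"probability column sums to {total}, not 1")
        if np.any(weights < 0):
            raise ValueError("negative probability in table")
    else:
        if np.any(weights < 0) or np.any(weights != np.round(weights)):
            raise ValueError("count column must hold nonnegative integers")
        total = weights.sum()
        if total == 0:
            raise ValueError("all-zero count table")
    levels = {c: sorted(df[c].unique()) for c in var_cols}
    vs = VariableSet(var_cols, [len(levels[c]) for c in var_cols])
    probs = np.zeros(tuple(vs.cardinalities))
    for row, w in zip(df[var_cols].itertuples(index=False), weights):
        idx = tuple(levels[c].index(v) for c, v in zip(var_cols, row))
        probs[idx] += w
    dist = DiscreteJointDistribution(vs, probs / probs.sum())
    dist.state_labels = levels  # type: ignore[attr-defined]
    return dist


def write_table(dist: DiscreteJointDistribution, path, sep: str = ",",
                labels: Mapping[str, Sequence[str]] | None = None) -> None:
    """Write the same format, rows in lexicographic state order."""
    vs = dist.variables
    labels = labels or getattr(dist, "state_labels", None) or {
        n: [str(i) for i in range(vs.cardinality(n))] for n in vs.names}
    rows = []
    for idx in itertools.product(*(range(c) for c in vs.cardinalities)):
        rows.append([labels[n][i] for n, i in zip(vs.names, idx)]
                    + [repr(float(dist.probs[idx]))])
    df = pd.DataFrame(rows, columns=list(vs.names) + ["p"])
    df = df.sort_values(list(vs.names), kind="stable")
    df.to_csv(path, sep=sep, index=False)
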