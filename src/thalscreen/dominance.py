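"""Dominance-based rough set approximations over preference-ordered data.

The dominance-based rough set approach (DRSA) replaces the indiscernibility
relation of classical rough sets with a dominance relation: object ``x``
dominates ``y`` when ``x`` is at least as good as ``y`` on every criterion
in the considered subset ``P``, where "at least as good" means ``>=`` for
gain-type criteria and ``<=`` for cost-type.  Decision classes are totally
ordered, and the objects of interest are the upward unions ``Cl>=t`` and
downward unions ``Cl<=t``.

Two dominance cones are attached to each object:

* ``dominating_set(x)`` -- objects that dominate ``x`` (``x``'s upward cone);
* ``dominated_set(x)``  -- objects dominated by ``x`` (downward cone).

Lower/upper approximations of the unions follow the classical DRSA
definitions: ``x`` certainly belongs to ``Cl>=t`` when its whole upward cone
lies inside the union, and possibly belongs when its downward cone meets it
(mirrored for downward unions).  Objects whose cones straddle a union form
its boundary; the fraction of objects outside every boundary is the quality
of approximation gamma.

Cone computation is the literal pairwise O(n^2 * m) algorithm, evaluated
in row blocks so memory stays linear in n for large tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Criterion",
    "DecisionTable",
    "ClassUnion",
    "ApproximationReport",
    "dominates",
    "dominating_set",
    "dominated_set",
    "class_unions",
    "lower_approximation",
    "upper_approximation",
    "boundary",
    "quality_of_approximation",
    "accuracy_of_approximation",
    "approximation_report",
]

GAIN = "gain"
COST = "cost"

_BLOCK = 256  # row-block size for the pairwise dominance matrix


@dataclass(frozen=True)
class Criterion:
    """A condition attribute with an explicit preference direction.

    ``gain``: larger values are more indicative of the preferred (higher)
    class; ``cost``: smaller values are.  The direction is mandatory —
    dominance is undefined without it.
    """

    name: str
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in (GAIN, COST):
            raise ValueError(
                f"criterion {self.name!r}: direction must be 'gain' or 'cost', "
                f"got {self.direction!r}"
            )


class DecisionTable:
    """Objects x criteria with ordinal decision classes.

    Parameters
    ----------
    data : DataFrame
        One row per object; must contain every criterion column and the
        decision column.  The index supplies object ids (must be unique).
    criteria : sequence of Criterion, or mapping name -> direction
    decision_col : name of the decision column (default ``"decision"``).
    class_order : decision classes from least to most preferred.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        criteria: Sequence[Criterion] | Mapping[str, str],
        decision_col: str = "decision",
        class_order: Sequence = (0, 1),
    ) -> None:
        if isinstance(criteria, Mapping):
            criteria = [Criterion(n, d) for n, d in criteria.items()]
        else:
            criteria = list(criteria)
        names = [c.name for c in criteria]
        if len(set(names)) != len(names):
            raise ValueError("duplicate criterion names")
        missing = [n for n in names if n not in data.columns]
        if missing:
            raise KeyError(f"criterion columns missing from data: {missing}")
        if decision_col not in data.columns:
            raise KeyError(f"decision column {decision_col!r} missing from data")
        if data.index.has_duplicates:
            raise ValueError("object ids (index) must be unique")
        if data[names].isna().any().any():
            raise ValueError("missing criterion values are not supported")
        class_order = list(class_order)
        bad = set(data[decision_col].unique()) - set(class_order)
        if bad:
            raise ValueError(f"decision classes outside class_order: {sorted(bad)}")

        self.criteria: list[Criterion] = criteria
        self.class_order = class_order
        self.decision_col = decision_col
        self.object_ids = list(data.index)
        self._pos = {oid: i for i, oid in enumerate(self.object_ids)}
        self.data = data
        self.decisions = np.asarray(
            [class_order.index(t) for t in data[decision_col]], dtype=np.int64
        )
        # orient values so dominance is uniformly ">=": negate cost columns
        vals = data[names].to_numpy(dtype=float)
        signs = np.array([1.0 if c.direction == GAIN else -1.0 for c in criteria])
        self._oriented = vals * signs
        self._names = names

    def __len__(self) -> int:
        return len(self.object_ids)

    @property
    def criterion_names(self) -> list[str]:
        return list(self._names)

    def direction_of(self, name: str) -> str:
        for c in self.criteria:
            if c.name == name:
                return c.direction
        raise KeyError(f"unknown criterion {name!r}")

    def subset_columns(self, P: Optional[Iterable[str]]) -> np.ndarray:
        """Oriented value matrix restricted to criteria subset ``P``."""
        if P is None:
            return self._oriented
        P = list(P)
        if not P:
            raise ValueError("criteria subset must be nonempty")
        try:
            cols = [self._names.index(p) for p in P]
        except ValueError as exc:
            raise KeyError(f"unknown criterion in subset: {exc}") from None
        return self._oriented[:, cols]

    def index_of(self, object_id) -> int:
        try:
            return self._pos[object_id]
        except KeyError:
            raise KeyError(f"unknown object id {object_id!r}") from None

    def restrict(self, object_ids: Sequence) -> "DecisionTable":
        """A new table over a subset of objects (criteria unchanged)."""
        return DecisionTable(
            self.data.loc[list(object_ids)],
            self.criteria,
            self.decision_col,
            self.class_order,
        )


@dataclass(frozen=True)
class ClassUnion:
    """Upward (``Cl>=t``) or downward (``Cl<=t``) union of decision classes."""

    kind: str  # "upward" | "downward"
    t: object  # class label
    members: frozenset

    def __post_init__(self) -> None:
        if self.kind not in ("upward", "downward"):
            raise ValueError(f"union kind must be 'upward' or 'downward', got {self.kind!r}")


def _member_mask(table: DecisionTable, union: ClassUnion) -> np.ndarray:
    rank = table.class_order.index(union.t)
    if union.kind == "upward":
        return table.decisions >= rank
    return table.decisions <= rank


def dominates(table: DecisionTable, x, y, P: Optional[Iterable[str]] = None) -> bool:
    """True iff ``x`` is at least as good as ``y`` on every criterion of ``P``."""
    V = table.subset_columns(P)
    ix, iy = table.index_of(x), table.index_of(y)
    return bool((V[ix] >= V[iy]).all())

def dominating_set(table: DecisionTable, x, P: Optional[Iterable[str]] = None) -> set:
    """Upward cone of ``x``: objects y with y dominating x (includes x)."""
    V = table.subset_columns(P)
    ix = table.index_of(x)
    mask = (V >= V[ix]).all(axis=1)
    return {table.object_ids[i] for i in np.flatnonzero(mask)}


def dominated_set(table: DecisionTable, x, P: Optional[Iterable[str]] = None) -> set:
    """Downward cone of ``x``: objects y dominated by x (includes x)."""
    V = table.subset_columns(P)
    ix = table.index_of(x)
    mask = (V <= V[ix]).all(axis=1)
    return {table.object_ids[i] for i in np.flatnonzero(mask)}


def class_unions(table: DecisionTable) -> list[ClassUnion]:
    """All upward and downward unions of the table's class order."""
    if not table.class_order:
        raise ValueError("class_order must be nonempty")
    ids = np.asarray(table.object_ids, dtype=object)
    unions = []
    for rank, t in enumerate(table.class_order):
        up = frozenset(ids[table.decisions >= rank])
        dn = frozenset(ids[table.decisions <= rank])
        unions.append(ClassUnion("upward", t, up))
        unions.append(ClassUnion("downward", t, dn))
    return unions


def _lower_mask(table: DecisionTable, P, union: ClassUnion) -> np.ndarray:
    """x is in the lower approximation iff its relevant cone stays inside
    the union: no outside object may dominate x (upward unions) and x may
    dominate no outside object (downward unions)."""
    member = _member_mask(table, union)
    V = table.subset_columns(P)
    out = member.copy()
    outside = np.flatnonzero(~member)
    for start in range(0, outside.size, _BLOCK):
        rows = outside[start : start + _BLOCK]
        if union.kind == "upward":
            # hit[o, x]: outside object o dominates x
            hit = (V[rows, None, :] >= V[None, :, :]).all(axis=-1)
        else:
            # hit[o, x]: x dominates outside object o
            hit = (V[rows, None, :] <= V[None, :, :]).all(axis=-1)
        out &= ~hit.any(axis=0)
    return out


def _upper_mask(table: DecisionTable, P, union: ClassUnion) -> np.ndarray:
    """x possibly belongs to an upward union iff x dominates some member,
    and to a downward union iff some member dominates x."""
    member = _member_mask(table, union)
    V = table.subset_columns(P)
    inside = np.flatnonzero(member)
    out = np.zeros(len(table), dtype=bool)
    for start in range(0, inside.size, _BLOCK):
        rows = inside[start : start + _BLOCK]
        if union.kind == "upward":
            # hit[m, x]: x dominates member m
            hit = (V[rows, None, :] <= V[None, :, :]).all(axis=-1)
        else:
            # hit[m, x]: member m dominates x
            hit = (V[rows, None, :] >= V[None, :, :]).all(axis=-1)
        out |= hit.any(axis=0)
    return out


def lower_approximation(
    table: DecisionTable, union: ClassUnion, P: Optional[Iterable[str]] = None
) -> set:
    """Objects certainly belonging to the union given dominance on ``P``."""
    mask = _lower_mask(table, P, union)
    return {table.object_ids[i] for i in np.flatnonzero(mask)}


def upper_approximation(
    table: DecisionTable, union: ClassUnion, P: Optional[Iterable[str]] = None
) -> set:
    """Objects possibly belonging to the union given dominance on ``P``."""
    mask = _upper_mask(table, P, union)
    return {table.object_ids[i] for i in np.flatnonzero(mask)}


def boundary(
    table: DecisionTable, union: ClassUnion, P: Optional[Iterable[str]] = None
) -> set:
    """Doubtful region: upper minus lower approximation."""
    lo = _lower_mask(table, P, union)
    up = _upper_mask(table, P, union)
    return {table.object_ids[i] for i in np.flatnonzero(up & ~lo)}


def quality_of_approximation(
    table: DecisionTable, P: Optional[Iterable[str]] = None
) -> float:
    """Fraction of objects outside every boundary region (gamma).

    1.0 means the table is dominance-consistent on ``P``.
    """
    if len(table) == 0:
        raise ValueError("quality of approximation is undefined on an empty table")
    in_boundary = np.zeros(len(table), dtype=bool)
    for union in class_unions(table):
        lo = _lower_mask(table, P, union)
        up = _upper_mask(table, P, union)
        in_boundary |= up & ~lo
    return float((~in_boundary).sum()) / len(table)


def accuracy_of_approximation(
    table: DecisionTable, union: ClassUnion, P: Optional[Iterable[str]] = None
) -> Optional[float]:
    """|lower| / |upper| for the union; None when the upper set is empty."""
    lo = _lower_mask(table, P, union)
    up = _upper_mask(table, P, union)
    n_up = int(up.sum())
    if n_up == 0:
        return None
    return float(lo.sum()) / n_up


@dataclass
class UnionApproximation:
    """Approximation of one class union."""

    kind: str
    t: object
    members: list
    lower: list
    upper: list
    boundary: list
    accuracy: Optional[float]


@dataclass
class ApproximationReport:
    """Lower/upper/boundary sets per union, per-union accuracy, global gamma."""

    criteria: list[str]
    unions: list[UnionApproximation]
    gamma: float

    def to_dict(self) -> dict:
        return {
            "criteria": self.criteria,
            "gamma": self.gamma,
            "unions": [
                {
                    "kind": u.kind,
                    "class": u.t,
                    "members": u.members,
                    "lower": u.lower,
                    "upper": u.upper,
                    "boundary": u.boundary,
                    "accuracy": u.accuracy,
                }
                for u in self.unions
            ],
        }

    def union(self, kind: str, t) -> UnionApproximation:
        for u in self.unions:
            if u.kind == kind and u.t == t:
                return u
        raise KeyError(f"no {kind} union for class {t!r}")

    def class_accuracy(self, t) -> Optional[float]:
        """Accuracy of the union characterizing class ``t``: the upward
        union for the top class, the downward union for the bottom class."""
        kind = "upward" if t == max(self.unions, key=lambda u: u.t).t else "downward"
        return self.union(kind, t).accuracy


def approximation_report(
    table: DecisionTable, P: Optional[Iterable[str]] = None
) -> ApproximationReport:
    """Full DRSA approximation analysis of a decision table on subset ``P``."""
    if len(table) == 0:
        raise ValueError("cannot build an approximation report on an empty table")
    names = list(P) if P is not None else table.criterion_names
    unions = []
    in_boundary = np.zeros(len(table), dtype=bool)

    def _sorted(ids: set) -> list:
        order = {oid: i for i, oid in enumerate(table.object_ids)}
        return sorted(ids, key=order.__getitem__)

    for union in class_unions(table):
        lo = _lower_mask(table, P, union)
        up = _upper_mask(table, P, union)
        bn = up & ~lo
        in_boundary |= bn
        n_up = int(up.sum())
        unions.append(
            UnionApproximation(
                kind=union.kind,
                t=union.t,
                members=_sorted(set(union.members)),
                lower=_sorted({table.object_ids[i] for i in np.flatnonzero(lo)}),
                upper=_sorted({table.object_ids[i] for i in np.flatnonzero(up)}),
                boundary=_sorted({table.object_ids[i] for i in np.flatnonzero(bn)}),
                accuracy=None if n_up == 0 else float(lo.sum()) / n_up,
            )
        )
    gamma = float((~in_boundary).sum()) / len(table)
    return ApproximationReport(criteria=names, unions=unions, gamma=gamma)
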