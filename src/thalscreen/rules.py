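"""Minimal decision-rule induction from (variable-consistency) lower
approximations — the DOMLEM family of sequential-covering learners.

Rules are conjunctions of elementary conditions ``(criterion >= v)`` /
``(criterion <= v)`` concluding ``Class >= t`` or ``Class <= t``.  For an
upward-union rule the relation is ``>=`` on gain criteria and ``<=`` on
cost criteria (mirrored for downward unions), so every rule respects the
monotone semantics of the dominance model.  Thresholds are always values
observed in the training data.

Induction is sequential covering per class union, most-preferred upward
union first: grow a rule by greedily adding the condition that maximizes
the covering ratio |cover ∩ G| / |cover| (G = still-uncovered positive
region), stop once the rule's cover lies inside the (variable-consistency)
positive region, prune redundant conditions, remove the newly covered
objects from G, and repeat until G is empty.  At consistency threshold
l = 1 this is plain DOMLEM on the ordinary lower approximations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .dominance import (
    COST,
    GAIN,
    ClassUnion,
    DecisionTable,
    _lower_mask,
    _member_mask,
    class_unions,
)

__all__ = [
    "ElementaryCondition",
    "DecisionRule",
    "RuleSet",
    "vc_positive_region",
    "induce_rules",
    "rule_metrics",
    "serialize_rules",
    "parse_rules",
    "RuleParseError",
]

AT_LEAST = "at_least"  # conclusion Class >= t
AT_MOST = "at_most"  # conclusion Class <= t


@dataclass(frozen=True)
class ElementaryCondition:
    """One ``criterion >= v`` or ``criterion <= v`` test."""

    criterion: str
    relation: str  # ">=" | "<="
    threshold: float

    def __post_init__(self) -> None:
        if self.relation not in (">=", "<="):
            raise ValueError(f"relation must be '>=' or '<=', got {self.relation!r}")
        object.__setattr__(self, "threshold", float(self.threshold))

    def holds(self, value: float) -> bool:
        return value >= self.threshold if self.relation == ">=" else value <= self.threshold

    def __str__(self) -> str:
        t = self.threshold
        printed = str(int(t)) if t == int(t) else repr(t)
        return f"({self.criterion}{self.relation}{printed})"


@dataclass(frozen=True)
class DecisionRule:
    """A conjunction of elementary conditions with a class-union conclusion.

    ``support`` (objects covered and correctly concluded on the training
    table) and ``consistency`` (fraction of covered objects in the
    concluded union) are training metadata and do not take part in rule
    equality, so a serialization round trip preserves identity.
    """

    conditions: tuple[ElementaryCondition, ...]
    kind: str  # AT_LEAST | AT_MOST
    t: int
    support: frozenset = field(default=frozenset(), compare=False)
    consistency: float = field(default=1.0, compare=False)

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("a decision rule needs at least one condition")
        if self.kind not in (AT_LEAST, AT_MOST):
            raise ValueError(f"rule kind must be at_least/at_most, got {self.kind!r}")
        seen = set()
        for c in self.conditions:
            key = (c.criterion, c.relation)
            if key in seen:
                raise ValueError(
                    f"duplicate condition on {c.criterion!r} with relation {c.relation}"
                )
            seen.add(key)

    def fires(self, record) -> bool:
        """True iff every condition holds on the record (a mapping or a
        pandas row); raises KeyError on a missing attribute."""
        return all(c.holds(record[c.criterion]) for c in self.conditions)

    def __str__(self) -> str:
        op = ">=" if self.kind == AT_LEAST else "<="
        body = "&".join(str(c) for c in self.conditions)
        return f"{body}=>(Class{op}{self.t})"


@dataclass
class RuleSet:
    """An ordered collection of induced rules plus induction metadata."""

    rules: list[DecisionRule]
    threshold: float = 1.0  # consistency level l used at induction
    criteria: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.rules)

    def __len__(self) -> int:
        return len(self.rules)

    def at_least_rules(self, t: Optional[int] = None) -> list[DecisionRule]:
        return [
            r
            for r in self.rules
            if r.kind == AT_LEAST and (t is None or r.t == t)
        ]


def vc_positive_region(
    table: DecisionTable,
    union: ClassUnion,
    l: float = 1.0,
    P: Optional[Iterable[str]] = None,
) -> set:
    """Variable-consistency positive region of a class union.

    A union member x is admitted when at least a fraction ``l`` of its
    relevant dominance cone (upward cone for upward unions, downward cone
    for downward unions) lies in the union.  At ``l = 1`` this equals the
    ordinary lower approximation.
    """
    if not 0 < l <= 1:
        raise ValueError(f"consistency threshold must lie in (0, 1], got {l}")
    member = _member_mask(table, union)
    V = table.subset_columns(P)
    out = []
    for i in np.flatnonzero(member):
        if union.kind == "upward":
            cone = (V >= V[i]).all(axis=1)  # objects dominating x
        else:
            cone = (V <= V[i]).all(axis=1)  # objects dominated by x
        if (cone & member).sum() / cone.sum() >= l:
            out.append(table.object_ids[i])
    return set(out)


def _relation_for(direction: str, kind: str) -> str:
    if kind == AT_LEAST:
        return ">=" if direction == GAIN else "<="
    return "<=" if direction == GAIN else ">="


def _cover_mask(values: np.ndarray, col: dict, conditions) -> np.ndarray:
    mask = np.ones(values.shape[0], dtype=bool)
    for c in conditions:
        v = values[:, col[c.criterion]]
        mask &= v >= c.threshold if c.relation == ">=" else v <= c.threshold
    return mask


def _grow_rule(values, col, relations, pos_mask, g_mask):
    """Grow one rule: greedy condition addition maximizing the covering
    ratio |cover ∩ G| / |cover|, ties broken by larger covered-G count,
    criterion name, then the less extreme threshold.

    Candidate thresholds are the values that the still-to-cover objects
    inside the current cover take; because a conjunction's cover is the
    intersection of its conditions' covers, each candidate is scored on
    the current cover alone, vectorized per criterion via sorting.  A
    tighter condition on an already-constrained criterion replaces the
    old one (a looser one cannot shrink the cover and is never chosen).
    May stop early without reaching the positive region when no candidate
    makes progress, which only happens at l < 1.
    """
    n = values.shape[0]
    conditions: dict[tuple[str, str], float] = {}
    cover = np.ones(n, dtype=bool)
    # a rule needs at least one condition even when the whole table already
    # lies inside the positive region
    while not conditions or (cover & ~pos_mask).any():
        cover_idx = np.flatnonzero(cover)
        best = None
        best_key = None
        for name in sorted(col):
            j = col[name]
            rel = relations[name]
            vals_cover = values[cover_idx, j]
            in_g = g_mask[cover_idx]
            thresholds = np.unique(vals_cover[in_g])
            if thresholds.size == 0:
                continue
            sv = np.sort(vals_cover)
            svg = np.sort(vals_cover[in_g])
            if rel == ">=":
                n_cov = sv.size - np.searchsorted(sv, thresholds, side="left")
                n_g = svg.size - np.searchsorted(svg, thresholds, side="left")
            else:
                n_cov = np.searchsorted(sv, thresholds, side="right")
                n_g = np.searchsorted(svg, thresholds, side="right")
            for t, nc, ng in zip(thresholds, n_cov, n_g):
                if ng == 0:
                    continue
                if conditions and nc == cover_idx.size:
                    continue  # a non-first condition must shrink the cover
                extremeness = t if rel == ">=" else -t
                key = (-(ng / nc), -ng, name, extremeness)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (name, rel, float(t))
        if best is None:
            break  # cannot be refined further (variable-consistency case)
        name, rel, t = best
        conditions[(name, rel)] = t
        column = values[:, col[name]]
        cover &= column >= t if rel == ">=" else column <= t
    conds = [ElementaryCondition(nm, rl, th) for (nm, rl), th in conditions.items()]
    return conds, cover


def _prune_rule(values, col, conditions, pos_mask):
    """Drop every condition whose removal keeps the cover inside the
    positive region; scan repeatedly until stable."""
    conditions = list(conditions)
    changed = True
    while changed and len(conditions) > 1:
        changed = False
        for c in list(conditions):
            rest = [x for x in conditions if x is not c]
            m = _cover_mask(values, col, rest)
            if (m & ~pos_mask).sum() == 0:
                conditions = rest
                changed = True
                break
    return conditions


def induce_rules(
    table: DecisionTable,
    P: Optional[Sequence[str]] = None,
    l: float = 1.0,
) -> RuleSet:
    """Induce a minimal covering rule set from the table's positive regions.

    Produces ``Class >= t`` rules for every non-bottom class (most
    preferred first) and ``Class <= t`` rules for every non-top class.
    Every object of each (VC-)positive region ends up covered by at least
    one of its union's rules; each rule is condition-minimal after pruning.
    """
    names = list(P) if P is not None else table.criterion_names
    if not names:
        raise ValueError("criteria subset must be nonempty")
    values = table.data[names].to_numpy(dtype=float)
    col = {name: j for j, name in enumerate(names)}
    directions = {name: table.direction_of(name) for name in names}

    unions = {(u.kind, u.t): u for u in class_unions(table)}
    order = list(table.class_order)
    targets = [("upward", t) for t in reversed(order[1:])] + [
        ("downward", t) for t in order[:-1]
    ]

    rules: list[DecisionRule] = []
    for kind_name, t in targets:
        union = unions[(kind_name, t)]
        rule_kind = AT_LEAST if kind_name == "upward" else AT_MOST
        relations = {n: _relation_for(directions[n], rule_kind) for n in names}
        pos = vc_positive_region(table, union, l, names)
        pos_mask = np.array([oid in pos for oid in table.object_ids])
        member = _member_mask(table, union)
        g_mask = pos_mask.copy()
        while g_mask.any():
            conditions, cover = _grow_rule(values, col, relations, pos_mask, g_mask)
            if not conditions:
                break  # positive region inseparable from the rest (l < 1)
            conditions = _prune_rule(values, col, conditions, pos_mask)
            cover = _cover_mask(values, col, conditions)
            covered_ids = frozenset(
                table.object_ids[i] for i in np.flatnonzero(cover & member)
            )
            consistency = float((cover & member).sum()) / int(cover.sum())
            rules.append(
                DecisionRule(
                    conditions=tuple(conditions),
                    kind=rule_kind,
                    t=t,
                    support=covered_ids,
                    consistency=consistency,
                )
            )
            g_mask &= ~cover
    return RuleSet(rules=rules, threshold=l, criteria=names)


def rule_metrics(rule: DecisionRule, table: DecisionTable) -> dict:
    """Support size, strength and confidence of a rule on a table."""
    for c in rule.conditions:
        if c.criterion not in table.criterion_names:
            raise KeyError(f"rule references unknown criterion {c.criterion!r}")
    values = table.data[[c.criterion for c in rule.conditions]].to_numpy(dtype=float)
    cover = np.ones(len(table), dtype=bool)
    for j, c in enumerate(rule.conditions):
        v = values[:, j]
        cover &= v >= c.threshold if c.relation == ">=" else v <= c.threshold
    union = ClassUnion(
        "upward" if rule.kind == AT_LEAST else "downward",
        rule.t,
        frozenset(),
    )
    member = _member_mask(table, union)
    n_cover = int(cover.sum())
    n_support = int((cover & member).sum())
    return {
        "support": n_support,
        "strength": n_support / len(table),
        "confidence": (n_support / n_cover) if n_cover else 0.0,
    }


class RuleParseError(ValueError):
    """Raised on malformed rule text; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_COND_RE = re.compile(r"\(\s*([A-Za-z_]\w*)\s*(>=|<=)\s*([-+]?[\d.]+(?:[eE][-+]?\d+)?)\s*\)")
_CONCL_RE = re.compile(r"=>\s*\(\s*Class\s*(>=|<=)\s*(\d+)\s*\)")


def _parse_rule_line(line: str, offset: int = 0) -> DecisionRule:
    m = _CONCL_RE.search(line)
    if m is None:
        raise RuleParseError("missing '=>(Class>=t)' conclusion", offset + len(line))
    body, concl_start = line[: m.start()], m.start()
    conditions = []
    pos = 0
    while pos < len(body):
        chunk = body[pos:].lstrip()
        skipped = len(body[pos:]) - len(chunk)
        pos += skipped
        if not chunk:
            break
        if conditions:
            if not chunk.startswith("&"):
                raise RuleParseError("expected '&' between conditions", offset + pos)
            pos += 1
            continue_from = body[pos:].lstrip()
            pos += len(body[pos:]) - len(continue_from)
        cm = _COND_RE.match(body, pos)
        if cm is None:
            raise RuleParseError("expected '(<attr><op><number>)'", offset + pos)
        conditions.append(
            ElementaryCondition(cm.group(1), cm.group(2), float(cm.group(3)))
        )
        pos = cm.end()
    if not conditions:
        raise RuleParseError("rule has no conditions", offset)
    kind = AT_LEAST if m.group(1) == ">=" else AT_MOST
    return DecisionRule(conditions=tuple(conditions), kind=kind, t=int(m.group(2)))


def serialize_rules(ruleset: RuleSet) -> str:
    """One rule per line in ``(attr>=v)&(attr<=v)=>(Class>=t)`` form."""
    return "\n".join(str(r) for r in ruleset.rules) + ("\n" if ruleset.rules else "")


def parse_rules(text: str, threshold: float = 1.0) -> RuleSet:
    """Parse a rules file (``#`` comments and blank lines ignored)."""
    rules = []
    offset = 0
    for line in text.splitlines():
        stripped = line.split("#", 1)[0].strip()
        if stripped:
            rules.append(_parse_rule_line(stripped, offset))
        offset += len(line) + 1
    criteria = sorted({c.criterion for r in rules for c in r.conditions})
    return RuleSet(rules=rules, threshold=threshold, criteria=criteria)
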