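"""Quality-preserving minimal criteria subsets (reducts).

A reduct is a subset ``P`` of the condition criteria whose quality of
approximation gamma equals that of the full criteria set, and from which
no criterion can be removed without lowering gamma.  Because gamma is
monotone under criterion addition, reducts can be found either by
exhaustive size-ordered enumeration (exact, exponential) or by backward
elimination (one reduct, polynomial).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

from .dominance import DecisionTable, quality_of_approximation

__all__ = ["Reduct", "is_reduct", "find_reducts", "core"]

EXHAUSTIVE_CRITERIA_CAP = 15


@dataclass(frozen=True)
class Reduct:
    criteria: tuple[str, ...]
    quality: float
    minimal: bool

    def to_dict(self, strategy: Optional[str] = None) -> dict:
        d = {"criteria": list(self.criteria), "quality": self.quality}
        if strategy is not None:
            d["strategy"] = strategy
        return d


def is_reduct(table: DecisionTable, P: Sequence[str]) -> tuple[bool, float]:
    """Whether ``P`` is a reduct; returns (verdict, gamma_P).

    ``P`` must preserve the full-set gamma AND be minimal: dropping any one
    criterion strictly lowers gamma.
    """
    P = list(P)
    if not P:
        raise ValueError("criteria subset must be nonempty")
    gamma_p = quality_of_approximation(table, P)
    gamma_full = quality_of_approximation(table)
    if gamma_p != gamma_full:
        return False, gamma_p
    if len(P) > 1:
        for name in P:
            rest = [c for c in P if c != name]
            if quality_of_approximation(table, rest) == gamma_full:
                return False, gamma_p
    return True, gamma_p


def _find_exhaustive(table: DecisionTable, gamma_full: float) -> list[Reduct]:
    names = sorted(table.criterion_names)
    found: list[frozenset] = []
    for size in range(1, len(names) + 1):
        for combo in combinations(names, size):
            s = frozenset(combo)
            # supersets of an already-found reduct are not minimal
            if any(r <= s for r in found):
                continue
            if quality_of_approximation(table, list(combo)) == gamma_full:
                found.append(s)
    return [
        Reduct(tuple(sorted(s)), gamma_full, True)
        for s in sorted(found, key=lambda s: (len(s), tuple(sorted(s))))
    ]


def _find_greedy(table: DecisionTable, gamma_full: float) -> list[Reduct]:
    """Backward elimination: repeatedly drop the criterion whose removal
    costs the least gamma (ties broken lexicographically by name), keeping
    a drop only if gamma is preserved; iterate to a fixpoint so the result
    is genuinely minimal."""
    current = sorted(table.criterion_names)
    changed = True
    while changed and len(current) > 1:
        changed = False
        losses = []
        for name in current:
            rest = [c for c in current if c != name]
            losses.append((gamma_full - quality_of_approximation(table, rest), name))
        for loss, name in sorted(losses):
            if loss == 0.0 and len(current) > 1:
                current = [c for c in current if c != name]
                changed = True
                break  # recompute losses on the shrunken set
    return [Reduct(tuple(current), gamma_full, True)]


def find_reducts(table: DecisionTable, strategy: str = "greedy") -> list[Reduct]:
    """Reducts of a decision table.

    ``strategy="exhaustive"`` returns all minimal quality-preserving
    subsets (refused above 15 criteria); ``"greedy"`` returns one reduct
    by deterministic backward elimination.
    """
    gamma_full = quality_of_approximation(table)
    if strategy == "exhaustive":
        if len(table.criterion_names) > EXHAUSTIVE_CRITERIA_CAP:
            raise ValueError(
                f"exhaustive reduct search is limited to "
                f"{EXHAUSTIVE_CRITERIA_CAP} criteria "
                f"({len(table.criterion_names)} given); use strategy='greedy'"
            )
        return _find_exhaustive(table, gamma_full)
    if strategy == "greedy":
        return _find_greedy(table, gamma_full)
    raise ValueError(f"unknown strategy {strategy!r}; use 'exhaustive' or 'greedy'")


def core(reducts: Sequence[Reduct]) -> set[str]:
    """Criteria common to every reduct (informational)."""
    if not reducts:
        return set()
    result = set(reducts[0].criteria)
    for r in reducts[1:]:
        result &= set(r.criteria)
    return result
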