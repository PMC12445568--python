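"""Independent exhaustive reference implementation of dominance rough sets.

Deliberately naive: plain Python dicts, sets and nested loops, sharing no
code with the package.  Tables are lists of ``(object_id, {criterion:
value}, class)`` triples plus a ``{criterion: "gain"|"cost"}`` direction
map; classes are integers ordered naturally.
"""

from itertools import combinations


def dominates(vx: dict, vy: dict, dirs: dict, P=None) -> bool:
    """x at least as good as y on every criterion of P."""
    for c in P if P is not None else dirs:
        if dirs[c] == "gain":
            if not vx[c] >= vy[c]:
                return False
        else:
            if not vx[c] <= vy[c]:
                return False
    return True


def dominating_set(table, dirs, x, P=None):
    vx = next(v for i, v, _ in table if i == x)
    return {i for i, v, _ in table if dominates(v, vx, dirs, P)}


def dominated_set(table, dirs, x, P=None):
    vx = next(v for i, v, _ in table if i == x)
    return {i for i, v, _ in table if dominates(vx, v, dirs, P)}


def union_members(table, kind, t):
    if kind == "up":
        return {i for i, _, c in table if c >= t}
    return {i for i, _, c in table if c <= t}


def lower(table, dirs, kind, t, P=None):
    members = union_members(table, kind, t)
    out = set()
    for i, _, _ in table:
        cone = dominating_set(table, dirs, i, P) if kind == "up" else dominated_set(table, dirs, i, P)
        if cone <= members:
            out.add(i)
    return out


def upper(table, dirs, kind, t, P=None):
    members = union_members(table, kind, t)
    out = set()
    for i, _, _ in table:
        cone = dominated_set(table, dirs, i, P) if kind == "up" else dominating_set(table, dirs, i, P)
        if cone & members:
            out.add(i)
    return out


def boundary(table, dirs, kind, t, P=None):
    return upper(table, dirs, kind, t, P) - lower(table, dirs, kind, t, P)


def gamma(table, dirs, P=None):
    classes = sorted({c for _, _, c in table})
    doubtful = set()
    for t in classes:
        for kind in ("up", "down"):
            doubtful |= boundary(table, dirs, kind, t, P)
    return len([1 for i, _, _ in table if i not in doubtful]) / len(table)


def accuracy(table, dirs, kind, t, P=None):
    up = upper(table, dirs, kind, t, P)
    if not up:
        return None
    return len(lower(table, dirs, kind, t, P)) / len(up)


def vc_positive(table, dirs, kind, t, l, P=None):
    members = union_members(table, kind, t)
    out = set()
    for i in members:
        cone = dominating_set(table, dirs, i, P) if kind == "up" else dominated_set(table, dirs, i, P)
        if len(cone & members) / len(cone) >= l:
            out.add(i)
    return out


def all_reducts(table, dirs):
    """All minimal gamma-preserving criteria subsets, by enumeration."""
    names = sorted(dirs)
    g_full = gamma(table, dirs)
    found = []
    for size in range(1, len(names) + 1):
        for combo in combinations(names, size):
            s = set(combo)
            if any(r <= s for r in found):
                continue
            if gamma(table, dirs, list(combo)) == g_full:
                found.append(s)
    return {frozenset(s) for s in found}
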