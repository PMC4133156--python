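"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (explicit loops, exhaustive scans)
and shares no code with the package's implementations.
"""

from __future__ import annotations

import itertools


# ----------------------------------------------------------------------
# simple directed cycles by DFS with path-set pruning
# ----------------------------------------------------------------------

def brute_force_cycles(edges: dict[tuple[str, str], int]) -> set[tuple[tuple[str, ...], int]]:
    """All simple directed cycles (canonical rotation: lexicographically
    smallest start) with their edge-sign products."""
    nodes = sorted({g for e in edges for g in e})
    succ: dict[str, list[str]] = {g: [] for g in nodes}
    for a, b in edges:
        succ[a].append(b)
    out: set[tuple[tuple[str, ...], int]] = set()

    def canon(path: list[str]) -> tuple[str, ...]:
        i = min(range(len(path)), key=lambda k: path[k])
        return tuple(path[i:]) + tuple(path[:i])

    def dfs(start: str, node: str, path: list[str], on_path: set[str]) -> None:
        for nxt in succ[node]:
            if nxt == start:
                cyc = canon(path)
                sign = 1
                for i in range(len(cyc)):
                    sign *= edges[(cyc[i], cyc[(i + 1) % len(cyc)])]
                out.add((cyc, sign))
            elif nxt not in on_path and nxt > start:
                # restrict to nodes > start so each cycle is found from its
                # smallest node only
                path.append(nxt)
                on_path.add(nxt)
                dfs(start, nxt, path, on_path)
                on_path.remove(nxt)
                path.pop()

    for g in nodes:
        dfs(g, g, [g], {g})
    return out


# ----------------------------------------------------------------------
# weighted evidence vote, recomputed longhand
# ----------------------------------------------------------------------

def brute_force_vote(lof, gof, chip, w_lof=2.0, w_gof=1.0):
    if chip == 0:
        return None
    if len(lof) == 0 and len(gof) == 0:
        return None
    total = 0.0
    for s in lof:
        total += w_lof * s
    for s in gof:
        total += w_gof * s
    if total > 0:
        return 1
    if total < 0:
        return -1
    return None


# ----------------------------------------------------------------------
# read-once formula scan for 2 and 3 variables
# ----------------------------------------------------------------------

def _eval2(op, a, b):
    return (a and b) if op == "AND" else (a or b)


def readonce_tables_2var() -> set[int]:
    """Distinct truth tables of (+/-A op +/-B), op in {AND, OR}."""
    tables = set()
    for op in ("AND", "OR"):
        for na in (False, True):
            for nb in (False, True):
                t = 0
                for pat in range(4):
                    a = bool(pat & 1) ^ na
                    b = bool(pat >> 1 & 1) ^ nb
                    if _eval2(op, a, b):
                        t |= 1 << pat
                tables.add(t)
    return tables


def readonce_tables_3var() -> set[int]:
    """Distinct truth tables over exactly variables {A, B, C}: both tree
    shapes ((x op y) op z and x op (y op z) over every leaf permutation),
    every operator assignment, every leaf negation pattern."""
    tables = set()
    for perm in itertools.permutations(range(3)):
        for op1 in ("AND", "OR"):
            for op2 in ("AND", "OR"):
                for negs in itertools.product((False, True), repeat=3):
                    for shape in ("left", "right"):
                        t = 0
                        for pat in range(8):
                            v = [bool(pat >> j & 1) for j in range(3)]
                            x, y, z = (v[perm[k]] ^ negs[k] for k in range(3))
                            if shape == "left":
                                val = _eval2(op2, _eval2(op1, x, y), z)
                            else:
                                val = _eval2(op2, x, _eval2(op1, y, z))
                            if val:
                                t |= 1 << pat
                        tables.add(t)
    return tables


# ----------------------------------------------------------------------
# synchronous dynamics: naive per-gene evaluation and full state graph
# ----------------------------------------------------------------------

def eval_tree(tree, parent_values: dict[str, int], parents: tuple[str, ...]) -> int:
    if tree[0] == "lit":
        _, j, neg = tree
        v = parent_values[parents[j]]
        return 1 - v if neg else v
    op, l, r = tree
    lv = eval_tree(l, parent_values, parents)
    rv = eval_tree(r, parent_values, parents)
    return (lv & rv) if op == "AND" else (lv | rv)


def naive_step(roster, rules, state: dict[str, int], clamped=frozenset()) -> dict[str, int]:
    """One synchronous update evaluated gene by gene from formula trees
    (constants carried as ("const", v))."""
    nxt = {}
    for g in roster:
        kind = rules[g]
        if kind[0] == "const":
            nxt[g] = kind[1]
        else:
            parents, tree = kind[1], kind[2]
            nxt[g] = eval_tree(tree, {p: state[p] for p in parents}, parents)
    for g in clamped:
        nxt[g] = 0
    return nxt


def naive_attractors(roster, rules, clamped=frozenset()):
    """Exact attractors and basin fractions from all 2**n_free initial
    states; attractor key = canonical tuple of packed states."""
    free = [g for g in roster if g not in clamped]

    def pack(state):
        s = 0
        for i, g in enumerate(roster):
            if state[g]:
                s |= 1 << i
        return s

    basins: dict[tuple[int, ...], int] = {}
    for combo in itertools.product((0, 1), repeat=len(free)):
        state = {g: 0 for g in roster}
        state.update(dict(zip(free, combo)))
        seen = {}
        traj = []
        while True:
            key = pack(state)
            if key in seen:
                cycle = traj[seen[key]:]
                k = cycle.index(min(cycle))
                canon = tuple(cycle[k:] + cycle[:k])
                basins[canon] = basins.get(canon, 0) + 1
                break
            seen[key] = len(traj)
            traj.append(key)
            state = naive_step(roster, rules, state, clamped)
    total = 2 ** len(free)
    return {k: v / total for k, v in basins.items()}
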