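"""Independent reference implementations used only by the tests.

Each oracle recomputes a quantity from first principles, along a code
path that shares nothing with the package implementation it checks.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# kinship / inbreeding


def recursive_kinship(parents: dict[str, tuple[str | None, str | None]]):
    """Kinship by direct recursion on its definition (memoised).

    ``f(a, a) = 0.5 (1 + f(sire_a, dam_a))``; for distinct animals the
    younger one is expanded: ``f(a, b) = 0.5 (f(sire_a, b) + f(dam_a, b))``.
    Unknown parents contribute 0.  ``parents`` must be insertion-ordered
    ancestors-first (that order defines "younger").
    """
    order = {a: k for k, a in enumerate(parents)}
    cache: dict[tuple[str, str], float] = {}

    def f(a: str | None, b: str | None) -> float:
        if a is None or b is None:
            return 0.0
        key = (a, b) if order[a] >= order[b] else (b, a)
        if key in cache:
            return cache[key]
        x, y = key  # x is the younger of the two
        s, d = parents[x]
        if x == y:
            val = 0.5 * (1.0 + f(s, d))
        else:
            val = 0.5 * (f(s, y) + f(d, y))
        cache[key] = val
        return val

    return f


def path_counting_inbreeding(parents: dict[str, tuple[str | None, str | None]]):
    """Wright's inbreeding by explicit path counting.

    ``F_X = Σ (1/2)^(n1+n2+1) (1 + F_A)`` over common ancestors ``A`` of
    X's parents and pairs of ancestral paths that share no animal except
    ``A``; ``n1, n2`` count the edges of each path.  Exponential in
    pedigree depth — fine for the ≤ 20-animal pedigrees it is used on.
    """

    def paths_up(x: str):
        """All upward paths from x: (endpoint, frozenset of nodes, n_edges)."""
        out = [(x, frozenset([x]), 0)]
        s, d = parents[x]
        for p in (s, d):
            if p is not None:
                for anc, nodes, n in paths_up(p):
                    out.append((anc, nodes | {x}, n + 1))
        return out

    memo: dict[str, float] = {}

    def F(x: str) -> float:
        if x in memo:
            return memo[x]
        s, d = parents[x]
        if s is None or d is None:
            memo[x] = 0.0
            return 0.0
        total = 0.0
        for anc1, nodes1, n1 in paths_up(s):
            for anc2, nodes2, n2 in paths_up(d):
                if anc1 == anc2 and nodes1 & nodes2 == frozenset([anc1]):
                    total += 0.5 ** (n1 + n2 + 1) * (1.0 + F(anc1))
        memo[x] = total
        return total

    return F


def random_pedigree(n: int, rng: np.random.Generator, founder_frac: float = 0.3):
    """Random acyclic pedigree as an ordered parent map (ancestors first)."""
    parents: dict[str, tuple[str | None, str | None]] = {}
    ids = [f"A{k}" for k in range(n)]
    n_founders = max(2, int(n * founder_frac))
    for k, a in enumerate(ids):
        if k < n_founders:
            parents[a] = (None, None)
        else:
            s, d = rng.choice(k, size=2, replace=True)
            parents[a] = (ids[int(s)], ids[int(d)])
    return parents


# ---------------------------------------------------------------------------
# use-vector constraint checking


def check_use_vector(nm, maxuse, minuse, absminuse, nt) -> list[str]:
    """Return a list of violated constraints (empty = legal)."""
    problems = []
    nm = np.asarray(nm)
    for i in range(len(nm)):
        lo = max(minuse[i], 1)
        if nm[i] < 0:
            problems.append(f"nm[{i}] negative")
        if nm[i] > maxuse[i]:
            problems.append(f"nm[{i}]={nm[i]} > maxuse {maxuse[i]}")
        if 0 < nm[i] < lo:
            problems.append(f"nm[{i}]={nm[i]} inside forbidden (0, {lo})")
        if absminuse[i] > 0 and nm[i] < absminuse[i]:
            problems.append(f"nm[{i}]={nm[i]} < absminuse {absminuse[i]}")
    if int(nm.sum()) != nt:
        problems.append(f"sum {int(nm.sum())} != nt {nt}")
    return problems


# ---------------------------------------------------------------------------
# step-by-step mate allocation (ungrouped driver)


def simulate_rank_allocation(male_ids, male_nm, rankings, female_ids, female_nm):
    """Re-enact the driver narrative one step at a time.

    Repeatedly find the highest remaining ranking value among unallocated
    male matings (ties: earlier male, then earlier slot) and hand it the
    leftmost unallocated female mating.
    """
    male_slots = [
        [i, r, float(rankings[i][r]), False]
        for i in range(len(male_ids))
        for r in range(int(male_nm[i]))
    ]
    female_slots = [
        [j, False] for j in range(len(female_ids)) for _ in range(int(female_nm[j]))
    ]
    pairs = []
    for _ in range(len(male_slots)):
        best = None
        for slot in male_slots:
            if slot[3]:
                continue
            if best is None or slot[2] > best[2]:
                best = slot
        best[3] = True
        for fs in female_slots:
            if not fs[1]:
                fs[1] = True
                pairs.append((str(male_ids[best[0]]), str(female_ids[fs[0]])))
                break
    return pairs
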