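"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by exhaustive enumeration or
generic solvers, staying independent of the package implementations they
check.
"""

from __future__ import annotations

import itertools
from typing import Dict, Mapping, Set, Tuple

import numpy as np
from scipy.optimize import linprog


def wang_s_values_bruteforce(term, parents, contrib) -> Dict[str, float]:
    """S-values by exhaustive upward-path enumeration.

    ``parents``: term -> set of (parent, relation).  S(t) is the maximum
    over all upward paths term -> ... -> t of the product of contribution
    factors along the path.
    """
    best = {term: 1.0}

    def walk(node, value):
        for parent, rel in parents.get(node, ()):
            v = value * contrib[rel]
            if v > best.get(parent, 0.0):
                best[parent] = v
            walk(parent, v)

    walk(term, 1.0)
    return best


def wang_similarity_bruteforce(a, b, parents, contrib) -> float:
    sa = wang_s_values_bruteforce(a, parents, contrib)
    sb = wang_s_values_bruteforce(b, parents, contrib)
    shared = set(sa) & set(sb)
    if not shared:
        return 0.0
    return sum(sa[t] + sb[t] for t in shared) / (sum(sa.values()) + sum(sb.values()))


def longest_depth_bruteforce(term, parents) -> int:
    """Longest path to a root by exhaustive path enumeration."""
    ps = parents.get(term, set())
    if not ps:
        return 0
    return 1 + max(longest_depth_bruteforce(p, parents) for p, _ in ps)


def wasserstein_lp(a, b) -> float:
    """Order-1 optimal transport between uniform empirical measures,
    solved as a linear program."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    m, n = len(a), len(b)
    cost = np.abs(a[:, None] - b[None, :]).ravel()
    A_eq = []
    b_eq = []
    for i in range(m):
        row = np.zeros(m * n)
        row[i * n:(i + 1) * n] = 1.0
        A_eq.append(row)
        b_eq.append(1.0 / m)
    for j in range(n):
        row = np.zeros(m * n)
        row[j::n] = 1.0
        A_eq.append(row)
        b_eq.append(1.0 / n)
    res = linprog(cost, A_eq=np.array(A_eq), b_eq=np.array(b_eq),
                  bounds=(0, None), method="highs")
    assert res.success
    return float(res.fun)


def welch_t_formula(a, b) -> Tuple[float, float]:
    """Welch's t and two-sided p from the textbook formulas."""
    from scipy.stats import t as tdist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * tdist.sf(abs(t), df)
    return float(t), float(p)


def random_dag(rng, n_terms: int) -> Dict[str, Set[Tuple[str, str]]]:
    """Random acyclic parent structure over ``n_terms`` ordered terms
    (parents only among earlier terms, so acyclicity is structural)."""
    names = [f"X{i}" for i in range(n_terms)]
    parents: Dict[str, Set[Tuple[str, str]]] = {names[0]: set()}
    for i in range(1, n_terms):
        k = int(rng.integers(0, min(i, 2) + 1))
        ps = set()
        for j in rng.choice(i, size=k, replace=False):
            rel = "is_a" if rng.uniform() < 0.7 else "part_of"
            ps.add((names[j], rel))
        parents[names[i]] = ps
    return parents
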