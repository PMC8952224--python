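"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by exhaustive enumeration or direct
definition, sharing no code with the implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

# ---------------------------------------------------------------------------
# duplex energy: exhaustive offset / maximal-run search

_PAIR_ORDER = ("CG", "GC", "GU", "UG", "AU", "UA")
_FLIP = {"CG": "GC", "GC": "CG", "GU": "UG", "UG": "GU", "AU": "UA", "UA": "AU"}


def brute_duplex(
    a: str, b: str, stack: np.ndarray, init: float, min_pair: int = 4
) -> tuple[float, float, int] | None:
    """Minimum (ndG, dG, length) over all antiparallel registers and maximal
    complementary runs, by direct enumeration."""
    code = {p: i for i, p in enumerate(_PAIR_ORDER)}
    a = a.upper().replace("T", "U")
    b = b.upper().replace("T", "U")
    n1, n2 = len(a), len(b)
    best = None
    for off in range(-(n2 - 1), n1):
        cells = []
        for i in range(n1):
            k = i - off
            if 0 <= k < n2:
                j = n2 - 1 - k
                cells.append(code.get(a[i] + b[j], -1))
        runs, run = [], []
        for p in cells:
            if p >= 0:
                run.append(p)
            elif run:
                runs.append(run)
                run = []
        if run:
            runs.append(run)
        for r in runs:
            if len(r) < min_pair:
                continue
            dg = init
            for p1, p2 in zip(r, r[1:]):
                dg += stack[p1][code[_FLIP[_PAIR_ORDER[p2]]]]
            key = (dg / len(r), dg, len(r))
            if best is None or key[:2] < best[:2]:
                best = key
    return best


# ---------------------------------------------------------------------------
# MCC: enumeration of maximal cliques over all vertex subsets


def brute_mcc(nodes: list, edges: set[tuple]) -> dict:
    """MCC per node by checking every vertex subset for maximal cliqueness."""
    import math

    adj = {n: set() for n in nodes}
    for (u, v) in edges:
        adj[u].add(v)
        adj[v].add(u)

    def is_clique(sub):
        return all(v in adj[u] for u, v in itertools.combinations(sub, 2))

    scores = {n: 0 for n in nodes}
    for r in range(2, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if not is_clique(sub):
                continue
            members = set(sub)
            # maximal iff no outside vertex adjacent to all members
            if any(members <= adj[w] for w in nodes if w not in members):
                continue
            w = math.factorial(r - 1)
            for n in sub:
                scores[n] += w
    return scores


# ---------------------------------------------------------------------------
# cis windows: all-pairs closest-edge distances


def brute_cis(lncs, genes, window):
    """All (lncRNA, gene) pairs within the window, by direct O(n^2) scan.

    Items are (id, chrom, strand, start, end) tuples; returns a set of
    (lnc_id, gene_id, signed_distance) with upstream negative relative to
    the lncRNA strand.
    """
    out = set()
    for (lid, lc, lstrand, ls, le) in lncs:
        for (gid, gc, _gs, gs, ge) in genes:
            if gc != lc or gid == lid:
                continue
            if gs > le:
                gap, left = gs - le, False
            elif ge < ls:
                gap, left = ls - ge, True
            else:
                gap, left = 0, False
            if gap > window:
                continue
            if gap == 0:
                out.add((lid, gid, 0))
            else:
                upstream = left if lstrand == "+" else not left
                out.add((lid, gid, -gap if upstream else gap))
    return out


# ---------------------------------------------------------------------------
# ORFs: every (start, stop) pair in three frames


def brute_longest_orf(seq: str) -> int:
    seq = seq.upper().replace("U", "T")
    stops = {"TAA", "TAG", "TGA"}
    best = 0
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        for j in range(i + 3, len(seq) - 2, 3):
            if seq[j : j + 3] in stops:
                best = max(best, j + 3 - i)
                break
    return best
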