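"""Independent oracles used by the test suite.

Everything here is deliberately brute-force and shares no code with the
package: per-column substitution counting for K2P, exhaustive unrooted
topology enumeration with least-squares branch fitting for NJ, and a full
(unbanded) Smith-Waterman via Biopython for the local aligner.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


def k2p_by_counting(a: str, b: str, min_overlap: int = 1):
    """Classify every column by hand, then evaluate the closed form."""
    n = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        both_pur = x in PURINES and y in PURINES
        both_pyr = x in PYRIMIDINES and y in PYRIMIDINES
        if both_pur or both_pyr:
            ts += 1
        else:
            tv += 1
    if n < min_overlap:
        return n, None
    P, Q = ts / n, tv / n
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        return n, None
    return n, -0.5 * math.log(w1 * math.sqrt(w2))


# ---- exhaustive unrooted-topology machinery -------------------------------
# Topologies are edge lists over leaf ids 0..n-1; internal ids start at n.

def enumerate_topologies(n: int) -> list[list[tuple[int, int]]]:
    trees = [([(0, n), (1, n), (2, n)], n + 1)]
    for leaf in range(3, n):
        nxt_trees = []
        for edges, nxt in trees:
            for ei, (a, b) in enumerate(edges):
                e2 = [e for j, e in enumerate(edges) if j != ei]
                e2 += [(a, nxt), (b, nxt), (leaf, nxt)]
                nxt_trees.append((e2, nxt + 1))
        trees = nxt_trees
    return [e for e, _ in trees]


def path_incidence(edges, n):
    """(pairs x edges) 0/1 matrix: which edges lie on each leaf-pair path."""
    adj: dict[int, list[tuple[int, int]]] = {}
    for ei, (a, b) in enumerate(edges):
        adj.setdefault(a, []).append((b, ei))
        adj.setdefault(b, []).append((a, ei))
    pairs = list(itertools.combinations(range(n), 2))
    M = np.zeros((len(pairs), len(edges)))
    for pi, (u, v) in enumerate(pairs):
        prev = {u: None}
        stack = [u]
        while stack:
            x = stack.pop()
            for y, ei in adj[x]:
                if y not in prev:
                    prev[y] = (x, ei)
                    stack.append(y)
        x = v
        while prev[x] is not None:
            px, ei = prev[x]
            M[pi, ei] = 1
            x = px
    return M, pairs


def random_additive_tree(n: int, rng):
    """Random unrooted binary tree with uniform branch lengths + its matrix."""
    edges = [(0, n), (1, n), (2, n)]
    nxt = n + 1
    for leaf in range(3, n):
        ei = int(rng.integers(0, len(edges)))
        a, b = edges[ei]
        edges = [e for j, e in enumerate(edges) if j != ei]
        edges += [(a, nxt), (b, nxt), (leaf, nxt)]
        nxt += 1
    lengths = rng.uniform(0.1, 2.0, len(edges))
    M, pairs = path_incidence(edges, n)
    D = np.zeros((n, n))
    for (i, j), d in zip(pairs, M @ lengths):
        D[i, j] = D[j, i] = d
    return edges, lengths, D


def splits_of_edges(edges, n) -> set[frozenset]:
    """Nontrivial splits, normalized to the side not containing leaf 0."""
    adj: dict[int, list[int]] = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    out = set()
    for a, b in edges:
        seen = {a, b}
        stack = [b]
        side = set()
        while stack:
            x = stack.pop()
            if x < n:
                side.add(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if 2 <= len(side) <= n - 2:
            out.add(frozenset(side) if 0 not in side else frozenset(set(range(n)) - side))
    return out


def best_fit_topologies(D: np.ndarray, topologies, incidences, pinvs, tol=1e-8):
    """Indices of topologies whose least-squares fit to D has ~zero residual."""
    n = D.shape[0]
    y = D[np.triu_indices(n, 1)]
    hits = []
    for idx, ((M, _), pinv) in enumerate(zip(incidences, pinvs)):
        beta = pinv @ y
        if np.linalg.norm(M @ beta - y) < tol:
            hits.append(idx)
    return hits


def smith_waterman_score(a: str, b: str, match, mismatch, gap_open, gap_extend):
    """Full (unbanded) local alignment optimum via Biopython's DP aligner."""
    from Bio import Align

    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al.score(a, b)


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), length))


def mutated_copy(rng, src: str, sub_rate=0.06, indel_prob=0.3) -> str:
    """A related sequence: point substitutions plus at most one short indel."""
    b = list(src)
    for i in range(len(b)):
        if rng.random() < sub_rate:
            b[i] = rng.choice(list("ACGT"))
    if rng.random() < indel_prob and len(b) > 30:
        pos = int(rng.integers(10, len(b) - 10))
        ln = int(rng.integers(1, 4))
        if rng.random() < 0.5:
            b = b[:pos] + b[pos + ln :]
        else:
            b = b[:pos] + list(rng.choice(list("ACGT"), ln)) + b[pos:]
    return "".join(b)
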