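"""Independent brute-force oracles used to validate the implementation.

Each oracle solves the same problem as a package operation by exhaustive
enumeration or dense search, sharing no code path with the implementation
it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


# ---------------------------------------------------------------------------
# maximum common connected subgraph (atom count), exhaustive growth


def mcs_size_oracle(elems_a, bonds_a, elems_b, bonds_b) -> int:
    """Largest connected element-matched common subgraph, by atom count.

    Grows every injective pair map that stays connected through edges
    present in both graphs; exhaustive for small graphs.
    """
    adj_a = _adj(len(elems_a), bonds_a)
    adj_b = _adj(len(elems_b), bonds_b)
    best = 0
    seen: set[frozenset] = set()

    def grow(mapped: dict[int, int], used_b: set[int]) -> None:
        nonlocal best
        key = frozenset(mapped.items())
        if key in seen:
            return
        seen.add(key)
        best = max(best, len(mapped))
        cands = set()
        for a, b in mapped.items():
            for a2 in adj_a[a]:
                if a2 in mapped:
                    continue
                for b2 in adj_b[b]:
                    if b2 not in used_b and elems_a[a2] == elems_b[b2]:
                        cands.add((a2, b2))
        for a2, b2 in sorted(cands):
            mapped[a2] = b2
            used_b.add(b2)
            grow(mapped, used_b)
            del mapped[a2]
            used_b.discard(b2)

    for a in range(len(elems_a)):
        for b in range(len(elems_b)):
            if elems_a[a] == elems_b[b]:
                grow({a: b}, {b})
    return best


def _adj(n: int, bonds) -> list[set[int]]:
    adj = [set() for _ in range(n)]
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    return adj


# ---------------------------------------------------------------------------
# global alignment by exhaustive path enumeration (affine gaps)


def nw_oracle(
    seq_a: str,
    seq_b: str,
    score_fn,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> tuple[float, set[float]]:
    """(optimal score, identity percents of all optimal alignments).

    A gap of length L costs ``gap_open + (L-1) * gap_extend``; end gaps are
    penalized identically.  Enumerates every global alignment — only usable
    for short sequences.
    """
    terminals: list[tuple[float, float]] = []

    def rec(i, j, score, ncols, nident, last):
        if i == len(seq_a) and j == len(seq_b):
            terminals.append((score, 100.0 * nident / ncols if ncols else 0.0))
            return
        if i < len(seq_a) and j < len(seq_b):
            s = score_fn(seq_a[i], seq_b[j])
            rec(i + 1, j + 1, score + s, ncols + 1,
                nident + (seq_a[i] == seq_b[j]), "M")
        if i < len(seq_a):
            cost = gap_extend if last == "GB" else gap_open
            rec(i + 1, j, score - cost, ncols + 1, nident, "GB")
        if j < len(seq_b):
            cost = gap_extend if last == "GA" else gap_open
            rec(i, j + 1, score - cost, ncols + 1, nident, "GA")

    rec(0, 0, 0.0, 0, 0, None)
    best = max(s for s, _i in terminals)
    idents = {i for s, i in terminals if abs(s - best) <= 1e-9}
    return best, idents


# ---------------------------------------------------------------------------
# minimal superposition RMSD by rotation-space search


def min_rmsd_bruteforce(
    A: np.ndarray, B: np.ndarray, n_grid: int = 20000, seed: int = 0
) -> float:
    """Dense random-quaternion grid over SO(3) plus a local polish.

    Centers both point sets (the optimal translation aligns centroids for
    any rotation), evaluates the RMSD at ``n_grid`` quasi-uniform random
    rotations, and refines the best one with a derivative-free local
    minimizer on the rotation vector.
    """
    A0 = A - A.mean(axis=0)
    B0 = B - B.mean(axis=0)
    n = len(A0)
    rots = Rotation.random(n_grid, rng=np.random.default_rng(seed))
    mats = rots.as_matrix()  # (N, 3, 3)
    rotated = np.einsum("nij,kj->nki", mats, B0)
    rmsds = np.sqrt(np.mean(np.sum((rotated - A0) ** 2, axis=2), axis=1))
    best_idx = int(np.argmin(rmsds))

    def f(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        d = B0 @ R.T - A0
        return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))

    res = minimize(
        f, rots[best_idx].as_rotvec(), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
    )
    return min(float(res.fun), float(rmsds[best_idx]))


# ---------------------------------------------------------------------------
# naive average-linkage agglomeration


def average_linkage_oracle(D: np.ndarray, cut: float) -> list[int]:
    """Labels after merging clusters while the minimal average distance <= cut.

    Direct O(n^3) re-implementation by repeated matrix scan; ties broken by
    the smallest involved member index.
    """
    n = len(D)
    clusters: list[list[int]] = [[i] for i in range(n)]

    def avg(c1, c2):
        return float(np.mean([D[i, j] for i in c1 for j in c2]))

    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = avg(clusters[a], clusters[b])
                key = (d, min(clusters[a] + clusters[b]))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, _tie), a, b = best
        if d > cut:
            break
        merged = sorted(clusters[a] + clusters[b])
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    labels = [0] * n
    for lab, c in enumerate(sorted(clusters, key=min)):
        for i in c:
            labels[i] = lab
    return labels


def partitions_equal(labels_a, labels_b) -> bool:
    """Same partition regardless of label numbering."""
    groups_a = {}
    groups_b = {}
    for i, l in enumerate(labels_a):
        groups_a.setdefault(l, set()).add(i)
    for i, l in enumerate(labels_b):
        groups_b.setdefault(l, set()).add(i)
    return set(map(frozenset, groups_a.values())) == set(map(frozenset, groups_b.values()))


# ---------------------------------------------------------------------------
# permutation test for the Pearson correlation p-value


def permutation_pvalue_counts(
    x: np.ndarray, y: np.ndarray, n_perm: int = 100_000, seed: int = 0
) -> tuple[int, int]:
    """(# permutations with |r| >= |r_observed|, n_perm) — two-sided."""
    rng = np.random.default_rng(seed)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    n = len(x)
    r_obs = abs(float(np.mean(xs * ys)))
    perm = np.array([rng.permutation(ys) for _ in range(n_perm)])
    r_perm = np.abs(perm @ xs / n)
    return int(np.sum(r_perm >= r_obs - 1e-12)), n_perm
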