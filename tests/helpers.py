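"""Independent oracle implementations and random fixture builders.

Everything here is deliberately naive (BFS, exhaustive enumeration,
O(n^3) loops, grid search) and shares no code with the package paths it
checks.
"""
from __future__ import annotations

import itertools

import numpy as np
import scipy.optimize
from scipy.spatial.transform import Rotation

from energyscape.database import LandscapeDatabase, Minimum, TransitionState


def bfs_partition(members, edges, u):
    """Connected components of the thresholded graph by breadth-first search.

    ``edges`` is an iterable of (energy, i, j); only edges with energy <= u
    and both endpoints in ``members`` count.  Returns a set of frozensets.
    """
    members = set(members)
    adj = {m: set() for m in members}
    for energy, i, j in edges:
        if energy <= u and i != j and i in members and j in members:
            adj[i].add(j)
            adj[j].add(i)
    seen = set()
    blocks = set()
    for start in members:
        if start in seen:
            continue
        queue, comp = [start], {start}
        seen.add(start)
        while queue:
            node = queue.pop(0)
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    comp.add(nxt)
                    queue.append(nxt)
        blocks.add(frozenset(comp))
    return blocks


def exhaustive_minimax_barrier(db: LandscapeDatabase, i: int, j: int):
    """Minimax barrier by enumerating every simple path (tiny databases only)."""
    if i == j:
        return db.energy(i)
    best_edge = {}
    for ts in db.transition_states:
        if ts.is_self_loop():
            continue
        key = (min(ts.i, ts.j), max(ts.i, ts.j))
        best_edge[key] = min(best_edge.get(key, np.inf), ts.energy)
    adj = {m.index: [] for m in db.minima}
    for (a, b), e in best_edge.items():
        adj[a].append((b, e))
        adj[b].append((a, e))
    best = [None]

    def walk(node, visited, path_max):
        if node == j:
            if best[0] is None or path_max < best[0]:
                best[0] = path_max
            return
        for nxt, e in adj[node]:
            if nxt not in visited:
                walk(nxt, visited | {nxt}, max(path_max, e))

    walk(i, {i}, -np.inf)
    return best[0]


def floyd_warshall(dist: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths with plain triple loops."""
    d = dist.copy()
    n = d.shape[0]
    for k in range(n):
        for a in range(n):
            for b in range(n):
                via = d[a, k] + d[k, b]
                if via < d[a, b]:
                    d[a, b] = via
    return d


def grid_search_rmsd(a: np.ndarray, b: np.ndarray, n_grid: int = 24) -> float:
    """Minimum RMSd over proper rotations by Euler-angle grid + refinement."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)

    def rmsd_of(angles):
        rot = Rotation.from_euler("zyx", angles).as_matrix()
        return np.sqrt(np.mean(np.sum((a - b @ rot.T) ** 2, axis=1)))

    grid = np.linspace(-np.pi, np.pi, n_grid, endpoint=False)
    best_angles, best = None, np.inf
    for angles in itertools.product(grid, grid[: n_grid // 2 + 1], grid):
        v = rmsd_of(angles)
        if v < best:
            best, best_angles = v, angles
    res = scipy.optimize.minimize(rmsd_of, best_angles, method="Nelder-Mead",
                                  options=dict(xatol=1e-10, fatol=1e-14,
                                               maxiter=2000))
    return float(min(best, res.fun))


def random_database(rng: np.random.Generator, n_min: int = 12,
                    n_edges: int = 18, parallel: bool = True,
                    connected: bool = True) -> LandscapeDatabase:
    """A random valid database: TS energies above both endpoints."""
    energies = rng.uniform(-10.0, 0.0, size=n_min)
    minima = [Minimum(index=k + 1, energy=float(e))
              for k, e in enumerate(energies)]
    tss = []
    if connected and n_min > 1:
        for k in range(2, n_min + 1):
            other = int(rng.integers(1, k))
            floor = max(energies[k - 1], energies[other - 1])
            tss.append(TransitionState(energy=float(floor + rng.uniform(0.2, 6.0)),
                                       i=k, j=other))
    for _ in range(n_edges):
        i, j = rng.integers(1, n_min + 1, size=2)
        if i == j and n_min > 1:
            continue
        floor = max(energies[i - 1], energies[j - 1])
        tss.append(TransitionState(energy=float(floor + rng.uniform(0.2, 6.0)),
                                   i=int(i), j=int(j)))
    if not parallel:
        seen, unique = set(), []
        for ts in tss:
            key = (min(ts.i, ts.j), max(ts.i, ts.j))
            if key not in seen:
                seen.add(key)
                unique.append(ts)
        tss = unique
    return LandscapeDatabase(minima, tss)


def label_match_accuracy(predicted: dict, truth: dict) -> float:
    """Best-relabeling agreement between two hard clusterings (greedy on
    the contingency table; exact when clusters correspond one-to-one)."""
    keys = sorted(truth)
    contingency = {}
    for k in keys:
        contingency.setdefault((predicted[k], truth[k]), 0)
        contingency[(predicted[k], truth[k])] += 1
    used_p, used_t, matched = set(), set(), 0
    for (p, t), c in sorted(contingency.items(), key=lambda kv: -kv[1]):
        if p not in used_p and t not in used_t:
            used_p.add(p)
            used_t.add(t)
            matched += c
    return matched / len(keys)
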