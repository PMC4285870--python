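"""Stationary-point databases: minima, transition states, connectivity.

The on-disk dialect follows the ``min.data`` / ``ts.data`` convention of
stationary-point sampling codes: whitespace-separated rows with the energy
in column 1.  Transition-state rows carry their two endpoint minimum
indices either in columns 4 and 5 (the full layout, whose columns 2-3 and
6+ hold frequency/point-group/inertia fields that are preserved opaquely)
or in columns 2 and 3 (a compact 3-column layout).  Minimum indices are
1-based in files and in every reported result.

Core queries: the sublevel set (minima connected to the global minimum
below a threshold energy U_t) and the minimax barrier between two minima
(the smallest possible value, over connecting paths, of the highest
transition-state energy en route).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

from . import fileio
from .geometry import as_coords

__all__ = [
    "Minimum",
    "TransitionState",
    "LandscapeDatabase",
    "SublevelSet",
    "DatabaseFormatError",
    "load_database",
    "write_database",
    "sublevel_set",
    "barrier_energy",
]

_FLOAT_FMT = "{:.17g}"


class DatabaseFormatError(ValueError):
    """A malformed database file; the message names file and line."""


@dataclass
class Minimum:
    """One local minimum: 1-based index, energy (eps), opaque extras."""

    index: int
    energy: float
    extra: tuple = ()

    def __post_init__(self):
        if not np.isfinite(self.energy):
            raise ValueError(f"minimum {self.index}: non-finite energy")


@dataclass
class TransitionState:
    """One transition state: energy (eps) and its two endpoint minima."""

    energy: float
    i: int
    j: int
    extra_mid: tuple = ()
    extra_tail: tuple = ()

    @property
    def endpoints(self):
        return (self.i, self.j)

    def is_self_loop(self) -> bool:
        return self.i == self.j


class LandscapeDatabase:
    """Minima plus transition states as an undirected weighted multigraph.

    Parallel transition states between the same pair of minima are kept as
    separate edges; only the lowest-energy one can ever determine a
    barrier.  Transition states connecting a minimum to itself are retained
    on output but ignored for connectivity.
    """

    def __init__(self, minima, transition_states, coordinates=None,
                 metadata=None):
        self.minima = list(minima)
        self.transition_states = list(transition_states)
        self.coordinates = coordinates  # dict: 1-based index -> (n, 3) array
        self.metadata = dict(metadata or {})
        if not self.minima:
            raise ValueError("a database needs at least one minimum")
        seen = set()
        for m in self.minima:
            if m.index in seen:
                raise ValueError(f"duplicate minimum index {m.index}")
            seen.add(m.index)
        for ts in self.transition_states:
            for end in ts.endpoints:
                if end not in seen:
                    raise ValueError(
                        f"transition state references unknown minimum {end}")
        if self.coordinates is not None:
            for idx, coords in self.coordinates.items():
                self.coordinates[idx] = as_coords(coords)

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.minima)

    @property
    def n_transition_states(self) -> int:
        return len(self.transition_states)

    def minimum(self, index: int) -> Minimum:
        try:
            return self._by_index[index]
        except AttributeError:
            self._by_index = {m.index: m for m in self.minima}
            return self.minimum(index)

    def energy(self, index: int) -> float:
        return self.minimum(index).energy

    @property
    def indices(self):
        return [m.index for m in self.minima]

    def global_minimum(self) -> Minimum:
        """Lowest-energy minimum; ties broken by lowest index."""
        return min(self.minima, key=lambda m: (m.energy, m.index))

    def has_coordinates(self) -> bool:
        return self.coordinates is not None

    def coords(self, index: int) -> np.ndarray:
        if self.coordinates is None or index not in self.coordinates:
            raise KeyError(f"no coordinates stored for minimum {index}")
        return self.coordinates[index]

    # -- graph views -------------------------------------------------------

    def graph(self, max_ts_energy: Optional[float] = None) -> nx.MultiGraph:
        """Connectivity multigraph; self-loops dropped, optional TS cap."""
        g = nx.MultiGraph()
        g.add_nodes_from(m.index for m in self.minima)
        for ts in self.transition_states:
            if ts.is_self_loop():
                continue
            if max_ts_energy is not None and ts.energy > max_ts_energy:
                continue
            g.add_edge(ts.i, ts.j, energy=ts.energy)
        return g

    def validate(self, clamp_ts: bool = False) -> int:
        """Report transition states lying below an endpoint's energy.

        Such rows are artefacts of real sampled databases; by default they
        are only warned about.  With ``clamp_ts=True`` each offending
        energy is raised to the higher endpoint energy.  Returns the count.
        """
        bad = 0
        for ts in self.transition_states:
            floor = max(self.energy(ts.i), self.energy(ts.j))
            if ts.energy < floor:
                bad += 1
                if clamp_ts:
                    ts.energy = floor
        if bad:
            action = "clamped to max(endpoint energies)" if clamp_ts else \
                "left as stored"
            warnings.warn(
                f"{bad} transition state(s) below an endpoint energy; {action}",
                stacklevel=2)
        return bad


# ---------------------------------------------------------------------------
# loading / writing


def _read_rows(path):
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            rows.append((lineno, stripped.split()))
    return rows


def load_database(min_table_path, ts_table_path, coords_path=None,
                  ts_format: str = "auto", coords_format: str = "auto",
                  clamp_ts: bool = False) -> LandscapeDatabase:
    """Load a database from its minima table, TS table and optional coordinates.

    Energies sit in column 1 of both tables.  ``ts_format``: ``"pathsample"``
    (endpoints in columns 4-5), ``"compact"`` (columns 2-3), or ``"auto"``
    to infer from the column count.  Coordinates are attached to minima in
    file order.
    """
    minima = []
    for lineno, toks in _read_rows(min_table_path):
        try:
            energy = float(toks[0])
        except ValueError as exc:
            raise DatabaseFormatError(
                f"{min_table_path}:{lineno}: non-numeric energy {toks[0]!r}"
            ) from exc
        minima.append(Minimum(index=len(minima) + 1, energy=energy,
                              extra=tuple(toks[1:])))
    if not minima:
        raise DatabaseFormatError(f"{min_table_path}: no minima rows")

    n = len(minima)
    tss = []
    resolved_format = ts_format
    for lineno, toks in _read_rows(ts_table_path):
        if resolved_format == "auto":
            if len(toks) >= 5:
                resolved_format = "pathsample"
            elif len(toks) == 3:
                resolved_format = "compact"
            else:
                raise DatabaseFormatError(
                    f"{ts_table_path}:{lineno}: cannot infer layout from "
                    f"{len(toks)} columns (expected >= 5 or exactly 3)")
        if resolved_format == "pathsample":
            if len(toks) < 5:
                raise DatabaseFormatError(
                    f"{ts_table_path}:{lineno}: expected >= 5 columns, "
                    f"got {len(toks)}")
            e_tok, i_tok, j_tok = toks[0], toks[3], toks[4]
            extra_mid, extra_tail = tuple(toks[1:3]), tuple(toks[5:])
        else:
            if len(toks) != 3:
                raise DatabaseFormatError(
                    f"{ts_table_path}:{lineno}: expected 3 columns, "
                    f"got {len(toks)}")
            e_tok, i_tok, j_tok = toks
            extra_mid, extra_tail = (), ()
        try:
            energy = float(e_tok)
        except ValueError as exc:
            raise DatabaseFormatError(
                f"{ts_table_path}:{lineno}: non-numeric energy {e_tok!r}") from exc
        try:
            i, j = int(i_tok), int(j_tok)
        except ValueError as exc:
            raise DatabaseFormatError(
                f"{ts_table_path}:{lineno}: non-integer endpoint "
                f"({i_tok!r}, {j_tok!r})") from exc
        for end in (i, j):
            if not (1 <= end <= n):
                raise DatabaseFormatError(
                    f"{ts_table_path}:{lineno}: endpoint {end} outside the "
                    f"{n}-minimum table")
        tss.append(TransitionState(energy=energy, i=i, j=j,
                                   extra_mid=extra_mid, extra_tail=extra_tail))

    coordinates = None
    if coords_path is not None:
        frames = fileio.read_coords(coords_path, fmt=coords_format)
        if len(frames) != n:
            raise DatabaseFormatError(
                f"{coords_path}: {len(frames)} structures for {n} minima")
        coordinates = {k + 1: frames[k] for k in range(n)}

    db = LandscapeDatabase(
        minima, tss, coordinates,
        metadata={"min_table": str(min_table_path),
                  "ts_table": str(ts_table_path),
                  "ts_format": resolved_format if tss else ts_format,
                  "units": {"energy": "eps", "length": "sigma"}})
    db.validate(clamp_ts=clamp_ts)
    return db


def write_database(db: LandscapeDatabase, min_table_path, ts_table_path,
                   coords_path=None, ts_format: Optional[str] = None,
                   coords_format: str = "flat") -> None:
    """Write tables (and optionally coordinates) re-loadable by ``load_database``."""
    if ts_format is None:
        ts_format = db.metadata.get("ts_format", "pathsample")
        if ts_format == "auto":
            ts_format = "pathsample"
    with open(min_table_path, "w") as fh:
        for m in db.minima:
            cols = [_FLOAT_FMT.format(m.energy), *m.extra]
            fh.write(" ".join(cols) + "\n")
    with open(ts_table_path, "w") as fh:
        for ts in db.transition_states:
            if ts_format == "pathsample":
                mid = ts.extra_mid if len(ts.extra_mid) == 2 else ("0", "0")
                cols = [_FLOAT_FMT.format(ts.energy), *mid,
                        str(ts.i), str(ts.j), *ts.extra_tail]
            elif ts_format == "compact":
                cols = [_FLOAT_FMT.format(ts.energy), str(ts.i), str(ts.j)]
            else:
                raise ValueError(f"unknown ts_format {ts_format!r}")
            fh.write(" ".join(cols) + "\n")
    if coords_path is not None:
        if not db.has_coordinates():
            raise ValueError("database carries no coordinates to write")
        ordered = [db.coords(m.index) for m in db.minima]
        comments = [f"minimum {m.index} energy {_FLOAT_FMT.format(m.energy)}"
                    for m in db.minima]
        fileio.write_coords(coords_path, ordered, fmt=coords_format,
                            comments=comments)


# ---------------------------------------------------------------------------
# sublevel sets and barriers


@dataclass(frozen=True)
class SublevelSet:
    """Minima connected to the global minimum below a threshold energy U_t.

    Membership requires a path to the global minimum on which every
    intermediate minimum and every transition state lies at or below the
    threshold.
    """

    threshold: float
    members: tuple  # sorted 1-based indices
    database: LandscapeDatabase = field(repr=False, compare=False)

    @property
    def size(self) -> int:
        return len(self.members)

    def __contains__(self, index: int) -> bool:
        return index in set(self.members)

    def energies(self) -> np.ndarray:
        return np.array([self.database.energy(i) for i in self.members])

    def coords(self, index: int) -> np.ndarray:
        if index not in set(self.members):
            raise KeyError(f"minimum {index} is not a member")
        return self.database.coords(index)

    def coords_matrix(self) -> np.ndarray:
        """(size, n_beads, 3) stack of member coordinates, member order."""
        missing = [i for i in self.members
                   if not self.database.has_coordinates()
                   or i not in self.database.coordinates]
        if missing:
            raise ValueError(f"minima without coordinates: {missing}")
        return np.stack([self.database.coords(i) for i in self.members])


def sublevel_set(db: LandscapeDatabase, u_t: float) -> SublevelSet:
    """All minima connected to the global minimum below threshold ``u_t``."""
    gm = db.global_minimum()
    if u_t < gm.energy:
        raise ValueError(
            f"threshold {u_t} lies below the global minimum energy {gm.energy}")
    g = nx.Graph()
    g.add_nodes_from(m.index for m in db.minima if m.energy <= u_t)
    for ts in db.transition_states:
        if ts.is_self_loop() or ts.energy > u_t:
            continue
        if ts.i in g and ts.j in g:
            g.add_edge(ts.i, ts.j)
    members = tuple(sorted(nx.node_connected_component(g, gm.index)))
    return SublevelSet(threshold=float(u_t), members=members, database=db)


def barrier_energy(db: LandscapeDatabase, i: int, j: int):
    """Minimax barrier between minima ``i`` and ``j``.

    The minimum, over all connecting paths, of the maximum transition-state
    energy along the path — computed by a union-find sweep over transition
    states in order of increasing energy.  ``i == j`` returns the minimum's
    own energy; disconnected pairs return ``None``.
    """
    for idx in (i, j):
        db.minimum(idx)  # raises KeyError on invalid index
    if i == j:
        return db.energy(i)
    parent = {m.index: m.index for m in db.minima}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for ts in sorted(db.transition_states, key=lambda t: t.energy):
        if ts.is_self_loop():
            continue
        ri, rj = find(ts.i), find(ts.j)
        if ri != rj:
            parent[ri] = rj
        if find(i) == find(j):
            return float(ts.energy)
    return None
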