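"""Coarse-grained three-letter bead-chain protein model.

Each residue is one bead: hydrophoBic, hydrophiLic or Neutral.  The chain
energy is a sum of four terms,

    U = sum_bonds     K_r (R - R_e)^2
      + sum_angles    K_theta (theta - theta_e)^2
      + sum_torsions  A (1 + cos phi) + B (1 + cos 3 phi)
      + sum_nonbonded 4 eps [ C (sigma/R)^12 - D (sigma/R)^6 ]

with stiff harmonic bond and angle restraints.  The torsion coefficients
(A, B) and the nonbonded coefficients (C, D) are pure functions of the bead
labels: B-B pairs attract (C = D = 1), L with L or B is repulsive
(C = 2/3, D = -1), and any pair involving an N bead has no R^-6 term
(C = 1, D = 0).  A torsion with two or more N beads is flexible
(A = 0, B = 0.2), otherwise stiff (A = B = 1.2).

Energies are in units of eps and lengths in units of sigma throughout; both
default to 1 so all numbers are dimensionless.

The Go variant of the model removes the attractive R^-6 term from every
B-B pair that is not a contact of a supplied native structure, which
unfrustrates the landscape into a single folding funnel.
"""
from __future__ import annotations

import functools
import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.optimize

from .geometry import as_coords, kabsch_align, kabsch_rmsd, zigzag_chain

__all__ = [
    "BeadSequence",
    "BLNParams",
    "Conformation",
    "ContactMap",
    "SequenceParseError",
    "EvaluationError",
    "BLN69_SEQUENCE",
    "parse_bln_sequence",
    "bln_potential",
    "minimize_local",
    "basin_hop_sample",
    "interpolated_barrier",
    "MinimizeResult",
]

#: The 69-bead frustrated beta-barrel former used as the worked example.
BLN69_SEQUENCE = "B9N3(LB)4N3B9N3(LB)4N3B9N3(LB)5L"

_VALID_BEADS = frozenset("BLN")


class SequenceParseError(ValueError):
    """Raised for malformed run-length bead-sequence strings."""

    def __init__(self, message: str, position: int):
        super().__init__(f"position {position}: {message}")
        self.position = position


class EvaluationError(ValueError):
    """Raised when the potential cannot be evaluated (overlapping beads)."""


@dataclass(frozen=True)
class BeadSequence:
    """An expanded chain of B/L/N bead labels."""

    beads: tuple

    def __post_init__(self):
        if len(self.beads) < 1:
            raise ValueError("empty bead sequence")
        bad = set(self.beads) - _VALID_BEADS
        if bad:
            raise ValueError(f"invalid bead labels {sorted(bad)}; allowed: B, L, N")

    def __len__(self) -> int:
        return len(self.beads)

    def __str__(self) -> str:
        return "".join(self.beads)

    def counts(self) -> dict:
        return {lab: self.beads.count(lab) for lab in "BLN"}


def parse_bln_sequence(spec: str) -> BeadSequence:
    """Expand a run-length sequence string like ``"B9N3(LB)4"``.

    Letters B/L/N may carry an integer repeat count; parenthesised groups
    may too.  Errors report the offending character position (0-based).
    """
    tokens = re.findall(r"[BLN]|\(|\)|\d+|\s+|.", spec)
    pos = 0
    stack = [[]]
    open_positions = []
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        if tok.isspace():
            pos += len(tok)
            i += 1
            continue
        if tok in _VALID_BEADS:
            unit = [tok]
        elif tok == "(":
            stack.append([])
            open_positions.append(pos)
            pos += 1
            i += 1
            continue
        elif tok == ")":
            if len(stack) == 1:
                raise SequenceParseError("unmatched ')'", pos)
            unit = stack.pop()
            open_positions.pop()
            if not unit:
                raise SequenceParseError("empty group", pos)
        elif tok.isdigit():
            raise SequenceParseError(f"repeat count '{tok}' without a preceding bead or group", pos)
        else:
            raise SequenceParseError(f"unknown character {tok!r}", pos)
        tok_len = len(tok)
        # optional repeat count after a bead letter or a closed group
        if i + 1 < len(tokens) and tokens[i + 1].isdigit():
            count = int(tokens[i + 1])
            if count <= 0:
                raise SequenceParseError(f"repeat count must be positive, got {count}",
                                         pos + tok_len)
            tok_len += len(tokens[i + 1])
            i += 1
        else:
            count = 1
        stack[-1].extend(unit * count)
        pos += tok_len
        i += 1
    if len(stack) > 1:
        raise SequenceParseError("unclosed '('", open_positions[-1])
    if not stack[0]:
        raise SequenceParseError("empty sequence", 0)
    return BeadSequence(beads=tuple(stack[0]))


@dataclass(frozen=True)
class BLNParams:
    """Force-field parameters (energies in eps, lengths in sigma).

    ``torsion_window`` selects which beads of a four-bead torsion are
    counted when testing the "two or more N beads" rule: ``"all"`` counts
    all four beads, ``"central"`` only the two middle ones.  Both readings
    of the rule are defensible; ``"all"`` is the default.
    """

    k_r: float = 231.2
    r_e: float = 1.0
    k_theta: float = 20.0
    theta_e: float = 1.8326
    epsilon: float = 1.0
    sigma: float = 1.0
    l_pair_c: float = 2.0 / 3.0
    torsion_window: str = "all"
    nonbonded_min_separation: int = 3
    min_distance: float = 1e-6

    def __post_init__(self):
        for name in ("k_r", "k_theta", "epsilon", "sigma", "r_e"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.torsion_window not in ("all", "central"):
            raise ValueError("torsion_window must be 'all' or 'central'")
        if self.nonbonded_min_separation < 1:
            raise ValueError("nonbonded_min_separation must be >= 1")


@dataclass
class Conformation:
    """Cartesian coordinates of one chain structure."""

    coords: np.ndarray
    sequence: BeadSequence

    def __post_init__(self):
        self.coords = as_coords(self.coords)
        if self.coords.shape[0] != len(self.sequence):
            raise ValueError(
                f"{self.coords.shape[0]} beads of coordinates for a "
                f"{len(self.sequence)}-bead sequence")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class ContactMap:
    """Unordered bead-index pairs in contact (indices 0-based, i < j)."""

    pairs: frozenset
    n_beads: int
    exclusion: int = 3

    def __post_init__(self):
        for i, j in self.pairs:
            if not (0 <= i < j < self.n_beads):
                raise ValueError(f"contact pair ({i}, {j}) out of range")
            if j - i <= self.exclusion:
                raise ValueError(
                    f"contact pair ({i}, {j}) inside the sequence-neighbour "
                    f"exclusion window |i-j| <= {self.exclusion}")

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self.pairs

    @classmethod
    def from_coordinates(cls, coords, cutoff: float = 1.167,
                         exclusion: int = 3) -> "ContactMap":
        """Contacts of a structure: pairs strictly closer than ``cutoff``,
        excluding pairs within ``exclusion`` beads along the sequence."""
        coords = as_coords(coords)
        n = coords.shape[0]
        ii, jj = np.triu_indices(n, k=exclusion + 1)
        d = np.linalg.norm(coords[ii] - coords[jj], axis=1)
        sel = d < cutoff
        pairs = frozenset((int(i), int(j)) for i, j in zip(ii[sel], jj[sel]))
        return cls(pairs=pairs, n_beads=n, exclusion=exclusion)


# ---------------------------------------------------------------------------
# interaction tables


@functools.lru_cache(maxsize=64)
def _interaction_tables(sequence: BeadSequence, params: BLNParams,
                        variant: str, native: Optional[ContactMap]):
    labels = sequence.beads
    n = len(labels)
    # torsion coefficients, one per four-bead run
    n_tor = max(n - 3, 0)
    A = np.empty(n_tor)
    B = np.empty(n_tor)
    for t in range(n_tor):
        if params.torsion_window == "all":
            window = labels[t:t + 4]
        else:
            window = labels[t + 1:t + 3]
        if sum(1 for lab in window if lab == "N") >= 2:
            A[t], B[t] = 0.0, 0.2
        else:
            A[t], B[t] = 1.2, 1.2
    # nonbonded pair coefficients
    sep = params.nonbonded_min_separation
    ii, jj = np.triu_indices(n, k=sep)
    C = np.empty(ii.size)
    D = np.empty(ii.size)
    for p, (i, j) in enumerate(zip(ii, jj)):
        a, b = labels[i], labels[j]
        if "N" in (a, b):
            C[p], D[p] = 1.0, 0.0
        elif a == "B" and b == "B":
            C[p], D[p] = 1.0, 1.0
        else:  # L with L or B
            C[p], D[p] = params.l_pair_c, -1.0
    if variant == "go":
        # only pairs eligible as contacts (outside the sequence-neighbour
        # exclusion window) can be non-native; closer pairs keep their term
        for p, (i, j) in enumerate(zip(ii, jj)):
            if D[p] > 0 and j - i > native.exclusion and \
                    (int(i), int(j)) not in native:
                D[p] = 0.0
    for arr in (A, B, C, D, ii, jj):
        arr.setflags(write=False)
    return A, B, C, D, ii, jj


def bln_potential(conf: Conformation, params: BLNParams = BLNParams(),
                  variant: str = "bln", native: Optional[ContactMap] = None):
    """Energy (eps) and analytic gradient (eps/sigma, shape ``(n, 3)``)."""
    if variant not in ("bln", "go"):
        raise ValueError("variant must be 'bln' or 'go'")
    if variant == "go" and native is None:
        raise ValueError("the go variant requires a native contact map")
    return _energy_gradient(conf.coords, conf.sequence, params, variant,
                            native if variant == "go" else None)


def _energy_gradient(coords, sequence, params, variant, native):
    coords = as_coords(coords)
    n = coords.shape[0]
    A, B, C, D, ii, jj = _interaction_tables(sequence, params, variant, native)
    energy = 0.0
    grad = np.zeros_like(coords)

    # bonds
    if n >= 2:
        disp = coords[1:] - coords[:-1]
        r = np.linalg.norm(disp, axis=1)
        dr = r - params.r_e
        energy += params.k_r * np.sum(dr ** 2)
        f = (2.0 * params.k_r * dr / r)[:, None] * disp  # dU/dr_{i+1}
        grad[1:] += f
        grad[:-1] -= f

    # angles
    if n >= 3:
        a = coords[:-2] - coords[1:-1]
        b = coords[2:] - coords[1:-1]
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        ah = a / na[:, None]
        bh = b / nb[:, None]
        cosv = np.clip(np.einsum("ij,ij->i", ah, bh), -1.0, 1.0)
        theta = np.arccos(cosv)
        sinv = np.maximum(np.sqrt(1.0 - cosv ** 2), 1e-8)
        energy += params.k_theta * np.sum((theta - params.theta_e) ** 2)
        du = 2.0 * params.k_theta * (theta - params.theta_e)
        dthe_i = (cosv[:, None] * ah - bh) / (na * sinv)[:, None]
        dthe_k = (cosv[:, None] * bh - ah) / (nb * sinv)[:, None]
        grad[:-2] += du[:, None] * dthe_i
        grad[2:] += du[:, None] * dthe_k
        grad[1:-1] -= du[:, None] * (dthe_i + dthe_k)

    # torsions
    if n >= 4:
        bvec = np.diff(coords, axis=0)
        b1, b2, b3 = bvec[:-2], bvec[1:-1], bvec[2:]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        x = np.einsum("ij,ij->i", n1, n2)
        y = np.einsum("ij,ij->i", np.cross(n1, n2), b2 / nb2[:, None])
        phi = np.arctan2(y, x)
        energy += np.sum(A * (1.0 + np.cos(phi)) + B * (1.0 + np.cos(3.0 * phi)))
        du = -A * np.sin(phi) - 3.0 * B * np.sin(3.0 * phi)
        sq1 = np.maximum(np.einsum("ij,ij->i", n1, n1), 1e-16)
        sq2 = np.maximum(np.einsum("ij,ij->i", n2, n2), 1e-16)
        f1 = -(nb2 / sq1)[:, None] * n1          # dphi/dr1
        f4 = (nb2 / sq2)[:, None] * n2           # dphi/dr4
        t = (np.einsum("ij,ij->i", b1, b2) / nb2 ** 2)[:, None]
        s = (np.einsum("ij,ij->i", b3, b2) / nb2 ** 2)[:, None]
        f2 = -(1.0 + t) * f1 + s * f4            # dphi/dr2
        f3 = t * f1 - (1.0 + s) * f4             # dphi/dr3
        duc = du[:, None]
        grad[:-3] += duc * f1
        grad[1:-2] += duc * f2
        grad[2:-1] += duc * f3
        grad[3:] += duc * f4

    # nonbonded pairs
    if ii.size:
        disp = coords[ii] - coords[jj]
        r = np.linalg.norm(disp, axis=1)
        if np.any(r < params.min_distance):
            k = int(np.argmin(r))
            raise EvaluationError(
                f"beads {int(ii[k])} and {int(jj[k])} overlap "
                f"(R = {r[k]:.3e} sigma)")
        inv6 = (params.sigma / r) ** 6
        inv12 = inv6 ** 2
        energy += 4.0 * params.epsilon * np.sum(C * inv12 - D * inv6)
        du_dr = 4.0 * params.epsilon * (-12.0 * C * inv12 + 6.0 * D * inv6) / r
        f = (du_dr / r)[:, None] * disp
        np.add.at(grad, ii, f)
        np.subtract.at(grad, jj, f)

    return float(energy), grad


# ---------------------------------------------------------------------------
# local minimization / basin-hopping


@dataclass
class MinimizeResult:
    """A locally minimized structure plus convergence diagnostics."""

    conformation: Conformation
    energy: float
    grad_norm: float
    converged: bool
    n_iter: int


def minimize_local(conf: Conformation, params: BLNParams = BLNParams(),
                   variant: str = "bln", native: Optional[ContactMap] = None,
                   gtol: float = 1e-6, max_iter: int = 20000) -> MinimizeResult:
    """Quasi-Newton (L-BFGS-B) descent to a nearby local minimum.

    Convergence means the final gradient infinity-norm is at most ``gtol``;
    a run that exhausts ``max_iter`` first is returned with
    ``converged=False``, never silently.
    """
    seq = conf.sequence

    def fun(x):
        e, g = _energy_gradient(x.reshape(-1, 3), seq, params, variant,
                                native if variant == "go" else None)
        return e, g.ravel()

    x0 = conf.coords.ravel().copy()
    e0, g0 = fun(x0)
    if np.max(np.abs(g0)) <= gtol:
        return MinimizeResult(conf, e0, float(np.max(np.abs(g0))), True, 0)
    res = scipy.optimize.minimize(
        fun, x0, jac=True, method="L-BFGS-B",
        options=dict(maxiter=max_iter, maxfun=max(10 * max_iter, 10),
                     ftol=0.0, gtol=0.3 * gtol))
    x = res.x if res.fun <= e0 else x0
    e, g = fun(x)
    gnorm = float(np.max(np.abs(g)))
    out = Conformation(coords=x.reshape(-1, 3), sequence=seq)
    return MinimizeResult(out, e, gnorm, gnorm <= gtol, int(res.nit))


def _is_duplicate(res: MinimizeResult, pool, energy_tol: float,
                  rmsd_tol: float) -> bool:
    for other in pool:
        if abs(res.energy - other.energy) <= energy_tol and \
                kabsch_rmsd(res.conformation.coords,
                            other.conformation.coords) <= rmsd_tol:
            return True
    return False


def basin_hop_sample(start: Conformation, params: BLNParams = BLNParams(),
                     n_steps: int = 100, step_size: float = 0.4,
                     temperature: float = 1.0, seed: int = 0,
                     variant: str = "bln", native: Optional[ContactMap] = None,
                     gtol: float = 1e-6,
                     energy_tol: float = 1e-6, rmsd_tol: float = 1e-3):
    """Basin-hopping walk collecting the distinct local minima visited.

    Random coordinate displacements followed by local minimization and a
    Metropolis test on minimized energies.  Minima are merged as duplicates
    when both the energy difference is within ``energy_tol`` and the Kabsch
    RMSd within ``rmsd_tol``.  A fixed ``seed`` reproduces the walk exactly.
    Returns the minima sorted by increasing energy.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    current = minimize_local(start, params, variant, native, gtol=gtol)
    minima = []
    if current.converged:
        minima.append(current)
    for _ in range(n_steps):
        trial_coords = current.conformation.coords + rng.uniform(
            -step_size, step_size, size=current.conformation.coords.shape)
        try:
            trial = minimize_local(
                Conformation(coords=trial_coords, sequence=start.sequence),
                params, variant, native, gtol=gtol)
        except EvaluationError:
            continue
        if trial.converged and not _is_duplicate(trial, minima, energy_tol, rmsd_tol):
            minima.append(trial)
        de = trial.energy - current.energy
        if trial.converged and (de <= 0 or rng.random() < np.exp(-de / temperature)):
            current = trial
    minima.sort(key=lambda m: m.energy)
    return minima


def interpolated_barrier(a: Conformation, b: Conformation,
                         params: BLNParams = BLNParams(), n_images: int = 51,
                         variant: str = "bln",
                         native: Optional[ContactMap] = None) -> float:
    """Highest energy along the straight-line path between two minima.

    ``b`` is Kabsch-aligned onto ``a`` first.  This is a crude upper-bound
    surrogate for a transition-state energy, not a true saddle point: the
    straight line generally passes above the lowest saddle.  The result is
    never below the energy of either endpoint (both are on the path).
    """
    if a.sequence != b.sequence:
        raise ValueError("conformations have different bead sequences")
    if n_images < 2:
        raise ValueError("need at least 2 images")
    R, t, _ = kabsch_align(a.coords, b.coords)
    b_aligned = b.coords @ R.T + t
    best = -np.inf
    for lam in np.linspace(0.0, 1.0, n_images):
        coords = (1.0 - lam) * a.coords + lam * b_aligned
        e, _ = _energy_gradient(coords, a.sequence, params, variant,
                                native if variant == "go" else None)
        best = max(best, e)
    return float(best)
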