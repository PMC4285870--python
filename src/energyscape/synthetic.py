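"""Deterministic generators of landscapes and ensembles with known truth.

Three generators back the test suite and the worked examples:

* a multi-funnel stationary-point database — each funnel is a random
  spanning tree of minima over low intra-funnel barriers, consecutive
  funnel bottoms joined by single high-energy transition states, and every
  minimum carries coordinates displaced along a planted structural axis by
  a per-funnel offset plus isotropic noise;
* a planted anisotropic Gaussian ensemble with known per-axis variances,
  hence known variance fractions for PCA to recover;
* a one-dimensional curved manifold in conformation space (a circular arc
  spanned by two orthonormal axes) with recorded arc-length order, on
  which geodesic embeddings succeed and straight-line projections fail
  once the arc bends far enough.

All planted axes are projected off the rigid-body subspace (translations
and infinitesimal rotations of the template chain), so the planted
structure survives the rotational alignment the metrics apply.  Every
generator is a pure function of its spec, seed included.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .database import LandscapeDatabase, Minimum, TransitionState, sublevel_set
from .geometry import zigzag_chain

__all__ = [
    "FunnelSpec",
    "GroundTruth",
    "generate_funnel_landscape",
    "generate_planted_gaussian",
    "generate_curved_manifold",
    "ensemble_members",
    "write_labels",
    "read_labels",
]


@dataclass(frozen=True)
class FunnelSpec:
    """Recipe for a synthetic multi-funnel stationary-point database.

    Energies in eps, displacements in sigma.  ``intra_barrier_range`` is
    measured above the higher endpoint of each intra-funnel transition
    state; ``inter_barrier`` above the highest funnel-bottom energy and
    must exceed every intra-funnel barrier so the funnels are genuinely
    separated.
    """

    n_funnels: int = 3
    minima_per_funnel: int = 25
    gm_energy: float = -100.0
    funnel_bottom_spacing: float = 1.0
    energy_spread: float = 3.0
    intra_barrier_range: tuple = (0.5, 2.0)
    inter_barrier: float = 10.0
    funnel_axis_spacing: float = 6.0
    noise_sd: float = 0.5
    n_beads: int = 48
    extra_edges: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_funnels < 1 or self.minima_per_funnel < 1:
            raise ValueError("counts must be >= 1")
        lo, hi = self.intra_barrier_range
        if not (0 < lo <= hi):
            raise ValueError("intra_barrier_range must be 0 < low <= high")
        if self.inter_barrier <= hi + self.energy_spread:
            raise ValueError(
                "inter_barrier must exceed energy_spread + the highest "
                "intra-funnel barrier for funnels to be separated")
        if self.n_beads < 4:
            raise ValueError("need at least 4 beads")


@dataclass(frozen=True, eq=False)
class GroundTruth:
    """What the generator planted, for tests to recover."""

    funnel_labels: dict = field(default=None)  # 1-based index -> funnel id
    planted_axis: np.ndarray = None  # unit vector, 3N
    planted_fractions: np.ndarray = None  # for Gaussian ensembles
    arc_parameter: np.ndarray = None  # for curved manifolds


def _rigid_subspace(template: np.ndarray) -> np.ndarray:
    """Orthonormal basis of rigid-body motions about a template structure."""
    n = template.shape[0]
    centered = template - template.mean(axis=0)
    basis = []
    for axis in range(3):
        v = np.zeros((n, 3))
        v[:, axis] = 1.0
        basis.append(v.ravel())
    for axis in range(3):
        e = np.zeros(3)
        e[axis] = 1.0
        basis.append(np.cross(e, centered).ravel())
    q, _ = np.linalg.qr(np.stack(basis).T)
    return q  # (3n, 6)


def _internal_axes(template: np.ndarray, n_axes: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Random orthonormal 3N axes orthogonal to the rigid-body subspace."""
    dim = template.size
    rigid = _rigid_subspace(template)
    axes = []
    while len(axes) < n_axes:
        v = rng.normal(size=dim)
        v -= rigid @ (rigid.T @ v)
        for a in axes:
            v -= a * (a @ v)
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            axes.append(v / norm)
    return np.stack(axes)


def generate_funnel_landscape(spec: FunnelSpec):
    """Build a multi-funnel database plus its ground truth.

    Funnel ``f`` has bottom energy ``gm_energy + f * funnel_bottom_spacing``
    and its remaining minima drawn uniformly within ``energy_spread`` above
    the bottom.  A random spanning tree (plus ``extra_edges`` shortcut
    edges) connects each funnel through transition states in
    ``intra_barrier_range`` above their higher endpoint; consecutive funnel
    bottoms are joined by single transition states at exactly
    ``max funnel bottom + inter_barrier``, so the minimax barrier between
    any cross-funnel pair equals that value.  Coordinates are the template
    chain displaced along a planted internal axis by
    ``f * funnel_axis_spacing`` plus isotropic noise of ``noise_sd``.
    """
    rng = np.random.default_rng(spec.seed)
    template = zigzag_chain(spec.n_beads)
    (axis,) = _internal_axes(template, 1, rng)

    minima = []
    labels = {}
    coords = {}
    tss = []
    bottoms = []
    for f in range(spec.n_funnels):
        bottom_e = spec.gm_energy + f * spec.funnel_bottom_spacing
        local = [bottom_e] + list(
            bottom_e + rng.uniform(0.0, spec.energy_spread,
                                   size=spec.minima_per_funnel - 1))
        first_idx = len(minima) + 1
        for e in local:
            idx = len(minima) + 1
            minima.append(Minimum(index=idx, energy=float(e)))
            labels[idx] = f
            disp = spec.funnel_axis_spacing * f * axis + \
                spec.noise_sd * rng.normal(size=template.size)
            coords[idx] = template + disp.reshape(-1, 3)
        bottoms.append(first_idx)
        # random spanning tree over this funnel's minima
        local_indices = list(range(first_idx, first_idx + len(local)))
        for pos in range(1, len(local_indices)):
            a = local_indices[pos]
            b = local_indices[int(rng.integers(0, pos))]
            e_ts = max(minima[a - 1].energy, minima[b - 1].energy) + \
                rng.uniform(*spec.intra_barrier_range)
            tss.append(TransitionState(energy=float(e_ts), i=a, j=b))
        for _ in range(spec.extra_edges):
            if len(local_indices) < 2:
                break
            a, b = rng.choice(local_indices, size=2, replace=False)
            if a == b:
                continue
            e_ts = max(minima[a - 1].energy, minima[b - 1].energy) + \
                rng.uniform(*spec.intra_barrier_range)
            tss.append(TransitionState(energy=float(e_ts), i=int(a), j=int(b)))

    top_bottom = spec.gm_energy + \
        (spec.n_funnels - 1) * spec.funnel_bottom_spacing
    inter_e = top_bottom + spec.inter_barrier
    for f in range(spec.n_funnels - 1):
        tss.append(TransitionState(energy=float(inter_e),
                                   i=bottoms[f], j=bottoms[f + 1]))

    db = LandscapeDatabase(minima, tss, coordinates=coords,
                           metadata={"generator": "funnel_landscape",
                                     "seed": spec.seed,
                                     "inter_funnel_ts_energy": inter_e})
    truth = GroundTruth(funnel_labels=labels, planted_axis=axis)
    return db, truth


def generate_planted_gaussian(n_samples: int, variances, seed: int = 0,
                              n_beads: int = 48):
    """Ensemble with known variance fractions along planted internal axes.

    Samples are ``template + sum_i sqrt(v_i) z_i axis_i`` with orthonormal
    axes and standard normal ``z``; the ground-truth fraction for axis i is
    ``v_i / sum(v)``.
    """
    variances = np.asarray(variances, dtype=float)
    if variances.ndim != 1 or variances.size < 1:
        raise ValueError("variances must be a non-empty 1-D sequence")
    if np.any(variances <= 0) or np.any(np.diff(variances) > 0):
        raise ValueError("variances must be positive and non-increasing")
    rng = np.random.default_rng(seed)
    template = zigzag_chain(n_beads)
    axes = _internal_axes(template, variances.size, rng)
    z = rng.normal(size=(n_samples, variances.size))
    disp = (z * np.sqrt(variances)) @ axes
    ensemble = template[None, :, :] + disp.reshape(n_samples, -1, 3)
    truth = GroundTruth(planted_axis=axes[0],
                        planted_fractions=variances / variances.sum())
    return ensemble, truth


def generate_curved_manifold(n_samples: int, curvature: float = 4.5,
                             seed: int = 0, n_beads: int = 48,
                             radius: float = 3.0):
    """Conformations along a planted circular arc in conformation space.

    The arc lives in the plane of two orthonormal internal axes:
    ``x(t) = radius (sin(curvature t) a1 + (1 - cos(curvature t)) a2)`` for
    ``t`` in [0, 1], so arc length grows linearly in ``t`` while the chord
    seen by any straight-line projection bends; for total winding beyond
    pi, no single linear direction rank-orders the samples, but geodesics
    still do.  Returns the ensemble (samples ordered by drawing, not by t)
    and ground truth holding the arc parameter of each sample.
    """
    if curvature <= 0:
        raise ValueError("curvature must be positive")
    rng = np.random.default_rng(seed)
    template = zigzag_chain(n_beads)
    a1, a2 = _internal_axes(template, 2, rng)
    t = np.sort(rng.uniform(0.0, 1.0, size=n_samples))
    disp = radius * (np.sin(curvature * t)[:, None] * a1 +
                     (1.0 - np.cos(curvature * t))[:, None] * a2)
    ensemble = template[None, :, :] + disp.reshape(n_samples, -1, 3)
    truth = GroundTruth(arc_parameter=t)
    return ensemble, truth


def ensemble_members(ensemble):
    """Wrap a bare conformation ensemble as a fully connected sublevel set.

    Gives generated ensembles (which have no energetics of their own) the
    member interface the metric routines expect: flat energies, a chain of
    formal transition states, sample ``k`` stored as minimum ``k + 1``.
    """
    ensemble = np.asarray(ensemble, dtype=float)
    minima = [Minimum(index=k + 1, energy=0.0) for k in range(len(ensemble))]
    tss = [TransitionState(energy=1.0, i=k + 1, j=k + 2)
           for k in range(len(ensemble) - 1)]
    coords = {k + 1: ensemble[k] for k in range(len(ensemble))}
    db = LandscapeDatabase(minima, tss, coordinates=coords,
                           metadata={"generator": "ensemble_members"})
    return sublevel_set(db, 1.0)


def write_labels(path, labels: dict) -> None:
    """Ground-truth funnel labels as two-column text (index, label)."""
    with open(path, "w") as fh:
        fh.write("# minimum funnel\n")
        for idx in sorted(labels):
            fh.write(f"{idx} {labels[idx]}\n")


def read_labels(path) -> dict:
    labels = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                idx, lab = line.split()
                labels[int(idx)] = int(lab)
    return labels
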