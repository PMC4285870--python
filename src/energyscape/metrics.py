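"""Structural order parameters over a sublevel set of minima.

Four metrics place minima along the horizontal axis of a metric
disconnectivity graph:

* fraction of native contacts N_alpha / N_NC — contacts are bead pairs
  strictly within 1.167 sigma, excluding pairs within three beads along
  the sequence;
* RMSd from a reference structure (the global minimum), minimized over
  proper rotations and translations with the Kabsch algorithm;
* principal components of the ensemble: iterative best-fit alignment of
  all structures onto their running average until the average stops
  drifting, then an SVD of the mean-centered configuration matrix.  The
  i-th metric is the projection of each minimum onto the i-th component.
  Components can also use an internal basis of dihedral sines/cosines;
* Isomap: geodesic distances approximated by shortest paths through the
  k-nearest-neighbour graph of the aligned ensemble, embedded by classical
  multidimensional scaling.  The i-th metric is the i-th embedded
  dimension.

Values are in sigma for RMSd / PC / Isomap metrics and dimensionless for
contact fractions.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse
import scipy.sparse.csgraph

from .bln import ContactMap
from .database import SublevelSet
from .geometry import as_coords, center, dihedral_angles, kabsch_align

__all__ = [
    "MetricSet",
    "PCAResult",
    "IsomapResult",
    "McLachlanResult",
    "native_contact_fraction",
    "contacts_metric",
    "rmsd_metric",
    "mclachlan_average",
    "dihedral_features",
    "pca_metric",
    "project_pc_structure",
    "isomap_metric",
]


@dataclass
class MetricSet:
    """Per-minimum scalar order-parameter values for one metric."""

    name: str
    values: dict  # 1-based minimum index -> float
    reference: Optional[object] = None  # minimum index or description

    def __post_init__(self):
        bad = [i for i, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite metric values for minima {bad}")

    def __getitem__(self, index: int) -> float:
        return self.values[index]

    def array(self, order) -> np.ndarray:
        return np.array([self.values[i] for i in order])

    def write(self, path) -> None:
        """Two-column delimited text: minimum index, value."""
        with open(path, "w") as fh:
            fh.write(f"# metric: {self.name}\n")
            fh.write(f"# reference: {self.reference}\n")
            for i in sorted(self.values):
                fh.write(f"{i} {self.values[i]:.17g}\n")

    @classmethod
    def read(cls, path) -> "MetricSet":
        name, reference = "metric", None
        values = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("# metric:"):
                    name = line.split(":", 1)[1].strip()
                elif line.startswith("# reference:"):
                    ref = line.split(":", 1)[1].strip()
                    reference = None if ref == "None" else ref
                elif line and not line.startswith("#"):
                    idx, val = line.split()
                    values[int(idx)] = float(val)
        return cls(name=name, values=values, reference=reference)


# ---------------------------------------------------------------------------
# native contacts


def native_contact_fraction(conf_coords, native: ContactMap,
                            cutoff: float = 1.167,
                            exclusion: int = 3) -> float:
    """Fraction of the native contact pairs realized by a conformation."""
    if len(native) == 0:
        raise ValueError("empty native contact map: fraction undefined")
    own = ContactMap.from_coordinates(conf_coords, cutoff=cutoff,
                                      exclusion=exclusion)
    return len(own.pairs & native.pairs) / len(native)


def contacts_metric(members: SublevelSet, reference: Optional[int] = None,
                    cutoff: float = 1.167, exclusion: int = 3) -> MetricSet:
    """Native-contact fraction of every member, native = reference structure.

    ``reference`` defaults to the global minimum.
    """
    db = members.database
    if reference is None:
        reference = db.global_minimum().index
    native = ContactMap.from_coordinates(db.coords(reference), cutoff=cutoff,
                                         exclusion=exclusion)
    values = {i: native_contact_fraction(members.coords(i), native,
                                         cutoff=cutoff, exclusion=exclusion)
              for i in members.members}
    return MetricSet(name="native_contacts", values=values, reference=reference)


# ---------------------------------------------------------------------------
# RMSd


def rmsd_metric(members: SublevelSet,
                reference: Optional[int] = None) -> MetricSet:
    """Kabsch RMSd of every member from a reference minimum (default: GM)."""
    db = members.database
    if reference is None:
        reference = db.global_minimum().index
    ref_coords = db.coords(reference)
    missing = [i for i in members.members
               if not db.has_coordinates() or i not in db.coordinates]
    if missing:
        raise ValueError(f"minima without coordinates: {missing}")
    values = {i: kabsch_align(ref_coords, db.coords(i))[2]
              for i in members.members}
    return MetricSet(name="rmsd", values=values, reference=reference)


# ---------------------------------------------------------------------------
# iterative ensemble alignment


@dataclass
class McLachlanResult:
    """Converged ensemble average and the aligned ensemble."""

    mean: np.ndarray  # (n, 3)
    aligned: np.ndarray  # (n_structures, n, 3)
    n_iter: int
    converged: bool
    s_history: list = field(default_factory=list)


def mclachlan_average(structures, s_tol: float = 1e-8,
                      max_iter: int = 200) -> McLachlanResult:
    """Iterative best-fit alignment of an ensemble onto its average.

    Every structure is centroid-centered, rotated onto the current average
    with the Kabsch algorithm, and the average recomputed, until the drift
    criterion s — the mean squared displacement of the average structure
    between successive iterations (sigma^2) — falls to ``s_tol``.
    Non-convergence within ``max_iter`` is flagged, never silent.
    """
    stack = np.stack([center(s) for s in structures])
    if stack.shape[0] < 2:
        raise ValueError("need at least two structures to average")
    mean = stack.mean(axis=0)
    history = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for k in range(stack.shape[0]):
            rot, _, _ = kabsch_align(mean, stack[k])
            stack[k] = stack[k] @ rot.T
        new_mean = stack.mean(axis=0)
        s = float(np.mean(np.sum((new_mean - mean) ** 2, axis=1)))
        history.append(s)
        mean = new_mean
        if s <= s_tol:
            converged = True
            break
    return McLachlanResult(mean=mean, aligned=stack, n_iter=n_iter,
                           converged=converged, s_history=history)


# ---------------------------------------------------------------------------
# dihedral features


def dihedral_features(conf_coords) -> np.ndarray:
    """Periodicity-free torsion features: (cos psi, sin psi) per dihedral.

    A chain of N beads has N-3 backbone torsions, so the feature vector has
    2(N-3) entries, ordered (cos psi_1, sin psi_1, cos psi_2, ...).  The
    features are invariant under rigid-body motion by construction.
    Collinear bead triples (undefined torsion) raise an error naming the
    quadruplet.
    """
    coords = as_coords(conf_coords)
    if coords.shape[0] < 4:
        raise ValueError("need at least 4 beads for a torsion")
    psi = dihedral_angles(coords, check=True)
    out = np.empty(2 * psi.size)
    out[0::2] = np.cos(psi)
    out[1::2] = np.sin(psi)
    return out


# ---------------------------------------------------------------------------
# principal components


def _fix_signs(components: np.ndarray, projections: np.ndarray):
    """Flip each component so its largest-magnitude entry is positive."""
    for k in range(components.shape[0]):
        lead = components[k, np.argmax(np.abs(components[k]))]
        if lead < 0:
            components[k] *= -1.0
            projections[:, k] *= -1.0
    return components, projections


@dataclass
class PCAResult:
    """Principal components of a conformational ensemble.

    ``components`` rows are orthonormal directions in feature space,
    ordered by decreasing variance; ``projections`` maps each minimum to
    its coordinates in that basis (the i-th PC metric is column i-1).
    """

    basis_kind: str  # "cartesian" or "dihedral"
    mean_structure: np.ndarray  # (n, 3) coords or feature vector
    components: np.ndarray  # (n_components, n_features)
    variances: np.ndarray  # descending
    fractions: np.ndarray  # variances / total, sums to 1
    projections: dict  # 1-based minimum index -> (n_components,) vector
    member_indices: tuple
    alignment: Optional[McLachlanResult] = field(default=None, repr=False)

    def metric_set(self, component: int = 1) -> MetricSet:
        """The ``component``-th principal-component metric (1-based)."""
        if not (1 <= component <= self.components.shape[0]):
            raise ValueError(f"component {component} out of range")
        values = {i: float(self.projections[i][component - 1])
                  for i in self.member_indices}
        return MetricSet(name=f"{self.basis_kind}_pc{component}",
                         values=values, reference=None)

    def project_structure(self, reference_coords, component: int = 1,
                          lam: float = 0.0) -> np.ndarray:
        """Displace a reference structure along a component by ``lam`` sigma."""
        return project_pc_structure(reference_coords,
                                    self.component_vector(component),
                                    lam, basis_kind=self.basis_kind)

    def component_vector(self, component: int = 1) -> np.ndarray:
        if not (1 <= component <= self.components.shape[0]):
            raise ValueError(f"component {component} out of range")
        return self.components[component - 1]


def pca_metric(members: SublevelSet, basis_kind: str = "cartesian",
               s_tol: float = 1e-8) -> PCAResult:
    """Principal component analysis of the sublevel-set ensemble.

    Cartesian mode first makes the ensemble rotation/translation-free by
    iterative best-fit alignment, then takes the SVD of the mean-centered
    configuration matrix; the covariance normalization is 1/N_sp
    (population), which leaves the variance fractions unchanged.  Dihedral
    mode uses the (cos, sin) torsion features, which need no alignment.
    """
    if basis_kind not in ("cartesian", "dihedral"):
        raise ValueError("basis_kind must be 'cartesian' or 'dihedral'")
    indices = members.members
    n_sp = len(indices)
    if n_sp < 2:
        raise ValueError("PCA needs at least two structures")
    stack = members.coords_matrix()
    alignment = None
    if basis_kind == "cartesian":
        alignment = mclachlan_average(stack, s_tol=s_tol)
        X = alignment.aligned.reshape(n_sp, -1)
        mean_structure = alignment.mean
    else:
        X = np.stack([dihedral_features(c) for c in stack])
        mean_structure = X.mean(axis=0)
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    variances = S ** 2 / n_sp
    total = variances.sum()
    fractions = variances / total if total > 0 else np.zeros_like(variances)
    projections_matrix = U * S  # = Xc @ Vt.T
    components, projections_matrix = _fix_signs(Vt.copy(), projections_matrix)
    projections = {idx: projections_matrix[k].copy()
                   for k, idx in enumerate(indices)}
    return PCAResult(basis_kind=basis_kind, mean_structure=mean_structure,
                     components=components, variances=variances,
                     fractions=fractions, projections=projections,
                     member_indices=tuple(indices), alignment=alignment)


def project_pc_structure(reference_coords, component: np.ndarray,
                         lam: float, basis_kind: str = "cartesian") -> np.ndarray:
    """Reference structure displaced along a Cartesian PC by ``lam`` sigma.

    Only Cartesian-basis components correspond to coordinate displacements;
    dihedral-basis components have no direct Cartesian back-projection and
    are rejected.
    """
    if basis_kind != "cartesian":
        raise ValueError("only cartesian-basis components can be "
                         "back-projected onto coordinates")
    coords = as_coords(reference_coords)
    component = np.asarray(component, dtype=float)
    if component.size != coords.size:
        raise ValueError(
            f"component length {component.size} != 3N = {coords.size}")
    if not np.isclose(np.linalg.norm(component), 1.0, atol=1e-8):
        raise ValueError("component must have unit norm")
    return coords + lam * component.reshape(coords.shape)


# ---------------------------------------------------------------------------
# Isomap


@dataclass
class IsomapResult:
    """Geodesic embedding of the sublevel-set ensemble."""

    k: int
    geodesics: np.ndarray  # (m, m) shortest-path distances, sigma (3N space)
    embedding: dict  # 1-based minimum index -> (n_dims,) vector
    embedded_indices: tuple  # members actually embedded (largest component)
    eigenvalues: np.ndarray
    graph_connected: bool
    distances: np.ndarray = field(repr=False, default=None)  # input distance matrix

    def metric_set(self, dim: int = 1) -> MetricSet:
        """The ``dim``-th embedded dimension as an order parameter (1-based)."""
        n_dims = next(iter(self.embedding.values())).size
        if not (1 <= dim <= n_dims):
            raise ValueError(f"dimension {dim} out of range")
        values = {i: float(v[dim - 1]) for i, v in self.embedding.items()}
        return MetricSet(name=f"isomap{dim}", values=values, reference=None)


def _pairwise_distance_matrix(stack: np.ndarray,
                              per_pair_kabsch: bool) -> np.ndarray:
    """Pairwise conformation distances in the full 3N space (sigma).

    This is sqrt(N) times the RMSd, so embedded axes come out in the same
    units as the principal-component metrics.
    """
    m, n, _ = stack.shape
    if per_pair_kabsch:
        d = np.zeros((m, m))
        for a in range(m):
            for b in range(a + 1, m):
                d[a, b] = d[b, a] = kabsch_align(stack[a], stack[b])[2]
        return d * np.sqrt(n)
    flat = stack.reshape(m, -1)
    sq = np.sum(flat ** 2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * flat @ flat.T, 0.0)
    np.fill_diagonal(d2, 0.0)
    d = np.sqrt(d2)
    return (d + d.T) / 2.0


def isomap_metric(members: SublevelSet, k: int = 15, n_dims: int = 2,
                  s_tol: float = 1e-8,
                  per_pair_kabsch: bool = False) -> IsomapResult:
    """Isomap embedding of the sublevel-set ensemble.

    The ensemble is first made rotation/translation-free by iterative
    best-fit alignment; pairwise conformation distances (by default
    fixed-frame in that common frame, which is a true metric; per-pair
    Kabsch-minimized via ``per_pair_kabsch=True``; either way scaled to
    the full 3N space, i.e. sqrt(N) times the RMSd, so the embedding
    shares units with the PC metrics) weight a k-nearest-neighbour graph,
    symmetrized by union.  All-pairs shortest paths through the graph
    approximate manifold geodesics, and classical multidimensional scaling
    of the geodesic matrix gives the embedding (eigenvectors scaled by the
    square root of their eigenvalues; negative eigenvalues truncated).  If
    the neighbour graph is disconnected, only the largest component is
    embedded, with a warning.
    """
    if n_dims < 1:
        raise ValueError("n_dims must be >= 1")
    indices = list(members.members)
    m = len(indices)
    if m <= k:
        raise ValueError(f"need more members ({m}) than neighbours (k={k})")
    stack = members.coords_matrix()
    alignment = mclachlan_average(stack, s_tol=s_tol)
    d = _pairwise_distance_matrix(alignment.aligned, per_pair_kabsch)

    # k-nearest-neighbour graph, symmetrized by union
    order = np.argsort(d, axis=1, kind="stable")
    rows, cols = [], []
    for a in range(m):
        for b in order[a, 1:k + 1]:
            rows.append(a)
            cols.append(int(b))
    w = scipy.sparse.csr_matrix((d[rows, cols], (rows, cols)), shape=(m, m))
    w = w.maximum(w.T)

    n_comp, labels = scipy.sparse.csgraph.connected_components(w, directed=False)
    graph_connected = n_comp == 1
    if graph_connected:
        keep = np.arange(m)
    else:
        sizes = np.bincount(labels)
        keep = np.where(labels == np.argmax(sizes))[0]
        warnings.warn(
            f"k-NN graph has {n_comp} components; embedding only the "
            f"largest ({keep.size} of {m} minima)", stacklevel=2)
        w = w[np.ix_(keep, keep)].tocsr()

    geo = scipy.sparse.csgraph.shortest_path(w, directed=False)

    # classical MDS on the geodesic matrix
    g2 = geo ** 2
    j = np.eye(keep.size) - np.ones((keep.size, keep.size)) / keep.size
    b = -0.5 * j @ g2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order_ev = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order_ev], eigvecs[:, order_ev]
    n_pos = int(np.sum(eigvals > 1e-12))
    n_keep = min(n_dims, max(n_pos, 1))
    lam = np.maximum(eigvals[:n_keep], 0.0)
    coords = eigvecs[:, :n_keep] * np.sqrt(lam)[None, :]
    comps, coords = _fix_signs(eigvecs[:, :n_keep].T.copy(), coords)

    embedded_indices = tuple(indices[i] for i in keep)
    embedding = {idx: coords[a].copy() for a, idx in enumerate(embedded_indices)}
    return IsomapResult(k=k, geodesics=geo, embedding=embedding,
                        embedded_indices=embedded_indices,
                        eigenvalues=eigvals, graph_connected=graph_connected,
                        distances=d)
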