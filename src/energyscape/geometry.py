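"""Chain geometry: construction, rigid superposition, internal coordinates.

Distances are dimensionless multiples of the bead diameter sigma; angles are
in radians.  Coordinates are ``(n, 3)`` arrays throughout.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "center",
    "rmsd_fixed_frame",
    "kabsch_align",
    "bond_angles",
    "dihedral_angles",
    "build_chain",
    "zigzag_chain",
    "random_rigid_motion",
]


def as_coords(x) -> np.ndarray:
    """Coerce a flat 3N vector or an (n, 3) array to (n, 3) float."""
    a = np.asarray(x, dtype=float)
    if a.ndim == 1:
        if a.size % 3:
            raise ValueError(f"flat coordinate vector of length {a.size} is not 3N")
        a = a.reshape(-1, 3)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"expected (n, 3) coordinates, got shape {a.shape}")
    return a


def center(coords: np.ndarray) -> np.ndarray:
    """Translate coordinates so the centroid sits at the origin."""
    coords = as_coords(coords)
    return coords - coords.mean(axis=0)


def rmsd_fixed_frame(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation without any superposition."""
    a, b = as_coords(a), as_coords(b)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_align(a: np.ndarray, b: np.ndarray):
    """Optimal proper superposition of structure ``b`` onto structure ``a``.

    Returns ``(rotation, translation, d)``: a proper 3x3 rotation matrix
    (determinant +1), a translation 3-vector, and the minimum RMSd ``d``
    over all proper rotations and translations.  ``coords @ rotation.T +
    translation`` maps ``b`` into the frame of ``a``.

    The singular-value decomposition branch corrects for reflections: when
    the cross-covariance has negative determinant the smallest singular
    direction is flipped, so a mirror image is never matched exactly.
    Degenerate (planar, collinear, n < 3) inputs take the same branch.
    """
    a, b = as_coords(a), as_coords(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    A, B = a - ca, b - cb
    H = B.T @ A
    U, _, Vt = np.linalg.svd(H)
    d_sign = np.sign(np.linalg.det(Vt.T @ U.T))
    if d_sign == 0:
        d_sign = 1.0
    D = np.diag([1.0, 1.0, d_sign])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    d = rmsd_fixed_frame(A, B @ R.T)
    return R, t, d


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSd between two structures over proper rigid motions."""
    return kabsch_align(a, b)[2]


def bond_angles(coords: np.ndarray) -> np.ndarray:
    """Angle at each interior bead between its two bonded neighbours."""
    coords = as_coords(coords)
    a = coords[:-2] - coords[1:-1]
    b = coords[2:] - coords[1:-1]
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    cosv = np.einsum("ij,ij->i", a, b) / (na * nb)
    return np.arccos(np.clip(cosv, -1.0, 1.0))


def dihedral_angles(coords: np.ndarray, check: bool = False,
                    degenerate_tol: float = 1e-10) -> np.ndarray:
    """Torsion angle for each run of four consecutive beads.

    Uses the atan2 form, which is well conditioned away from collinear
    triples.  With ``check=True`` a collinear triple (undefined torsion)
    raises ``ValueError`` naming the offending bead quadruplet.
    """
    coords = as_coords(coords)
    if coords.shape[0] < 4:
        return np.empty(0)
    b = np.diff(coords, axis=0)
    b1, b2, b3 = b[:-2], b[1:-1], b[2:]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if check:
        bad = np.where((np.linalg.norm(n1, axis=1) < degenerate_tol)
                       | (np.linalg.norm(n2, axis=1) < degenerate_tol))[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"torsion over beads ({i}, {i + 1}, {i + 2}, {i + 3}) is "
                "undefined: three consecutive beads are collinear")
    b2_hat = b2 / np.linalg.norm(b2, axis=1, keepdims=True)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2_hat)
    return np.arctan2(y, x)


def build_chain(n: int, bond: float = 1.0, angle: float = 1.8326,
                dihedrals=None) -> np.ndarray:
    """Build chain coordinates from internal coordinates.

    All bonds share one length and all bond angles one value; ``dihedrals``
    gives the n-3 torsions (default: all pi, a planar trans chain).
    """
    if n < 1:
        raise ValueError("need at least one bead")
    coords = np.zeros((n, 3))
    if n >= 2:
        coords[1] = [bond, 0.0, 0.0]
    if n >= 3:
        coords[2] = coords[1] + bond * np.array([-np.cos(angle), np.sin(angle), 0.0])
    if n >= 4:
        if dihedrals is None:
            dihedrals = np.full(n - 3, np.pi)
        dihedrals = np.asarray(dihedrals, dtype=float)
        if dihedrals.shape != (n - 3,):
            raise ValueError(f"expected {n - 3} dihedrals, got {dihedrals.shape}")
        for i in range(3, n):
            a, bb, c = coords[i - 3], coords[i - 2], coords[i - 1]
            phi = dihedrals[i - 3]
            bc = c - bb
            bc /= np.linalg.norm(bc)
            nrm = np.cross(bb - a, bc)
            nrm /= np.linalg.norm(nrm)
            m = np.cross(nrm, bc)
            d2 = bond * np.array([-np.cos(angle),
                                  np.sin(angle) * np.cos(phi),
                                  np.sin(angle) * np.sin(phi)])
            coords[i] = c + d2[0] * bc + d2[1] * m + d2[2] * nrm
    return coords


def zigzag_chain(n: int, bond: float = 1.0, angle: float = 1.8326) -> np.ndarray:
    """Planar all-trans chain, the default template/starting structure."""
    return build_chain(n, bond=bond, angle=angle)


def random_rigid_motion(rng: np.random.Generator):
    """A random proper rotation matrix and translation vector."""
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-5.0, 5.0, size=3)
    return R, t
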