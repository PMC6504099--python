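"""Rigid-body geometry: superposition, screw-axis decomposition, symmetry-type
classification and point-group perception.

A symmetry axis is the screw decomposition of the rigid transform that maps
each repeat onto the next: a rotation by ``theta`` about a line in space plus
a translation ``screw_t`` along that line.  Closed (point-group) symmetry has
negligible screw translation; open symmetry (helical/translational) does not.

Point groups are perceived from the repeat centroids by a near-uniform grid
search over rotation space (quaternions), the centroid-first strategy used
for protein-assembly symmetry perception: a candidate rotation must
first permute centroids onto centroids, and is then verified on all Ca atoms
of the aligned columns.  Valid rotations are closed under composition to
yield the group.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError
from .params import GeometryTolerances


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self o other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)

    def power(self, m: int) -> "RigidTransform":
        base = self if m >= 0 else self.inverse()
        out = RigidTransform.identity()
        for _ in range(abs(m)):
            out = base.compose(out)
        return out

    def angle_deg(self) -> float:
        return float(np.degrees(np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec())))


def superimpose(P: np.ndarray, Q: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of P onto Q (Kabsch).

    Returns the proper-rotation transform T minimizing RMSD(T(P), Q) and the
    achieved RMSD.  Raises :class:`DegenerateGeometryError` for fewer than 3
    points or a collinear point set.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching (n, 3) arrays")
    if len(P) < 3:
        raise DegenerateGeometryError("need at least 3 points to superimpose")
    cP = P.mean(axis=0)
    cQ = Q.mean(axis=0)
    Pc = P - cP
    Qc = Q - cQ
    sv = np.linalg.svd(Pc, compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise DegenerateGeometryError("point set is collinear")
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cQ - R @ cP
    T = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((T.apply(P) - Q) ** 2, axis=1))))
    return T, rmsd


# ---------------------------------------------------------------------------
# screw axes
# ---------------------------------------------------------------------------

@dataclass
class SymmetryAxis:
    """Screw decomposition of a repeat-to-repeat transform."""

    direction: np.ndarray
    point: np.ndarray
    theta_deg: float
    screw_t: float
    level: int = 0
    repeat_pairs: list = field(default_factory=list)

    def to_transform(self) -> RigidTransform:
        """Re-compose the rigid transform this axis decomposes."""
        R = Rotation.from_rotvec(np.radians(self.theta_deg) * self.direction).as_matrix()
        t = self.screw_t * self.direction + (np.eye(3) - R) @ self.point
        return RigidTransform(R, t)


def axis_from_transform(T: RigidTransform, level: int = 0) -> SymmetryAxis:
    """Screw-decompose a rigid transform into axis, angle and translation.

    For a (near) pure translation the direction is the translation direction
    with theta = 0.  The axis point is the minimum-norm solution of the
    fixed-point equation for the perpendicular translation component.
    """
    rotvec = Rotation.from_matrix(T.rotation).as_rotvec()
    angle = float(np.linalg.norm(rotvec))
    t = T.translation
    if angle < 1e-3:
        norm = float(np.linalg.norm(t))
        direction = t / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
        return SymmetryAxis(direction, np.zeros(3), 0.0, norm, level=level)
    direction = rotvec / angle
    screw_t = float(np.dot(t, direction))
    t_perp = t - screw_t * direction
    # (I - R) p = t_perp ; singular along the axis, use least squares
    point, *_ = np.linalg.lstsq(np.eye(3) - T.rotation, t_perp, rcond=None)
    point = point - np.dot(point, direction) * direction
    return SymmetryAxis(direction, point, float(np.degrees(angle)), screw_t, level=level)


def classify_axis(
    axis: SymmetryAxis,
    k: int,
    has_cp: bool,
    tol: GeometryTolerances = GeometryTolerances(),
    max_order: int = 8,
) -> str:
    """Symmetry-type token for one level from its consecutive-repeat axis.

    Closed (circularly permuted) levels are cyclic ``Cn``.  Open levels are
    ``R`` when either the screw translation or the rotation is negligible,
    ``Hn`` when the rotation is close to an integer fraction of a turn
    (n subunits per turn), ``SH`` otherwise.
    """
    if has_cp:
        return f"C{k}"
    theta = axis.theta_deg
    t = abs(axis.screw_t)
    if t <= tol.t_tol or theta <= tol.theta_tol:
        return "R"
    best_n, best_dev = None, np.inf
    for n in range(2, max_order + 1):
        dev = abs(theta - 360.0 / n)
        if dev < best_dev:
            best_n, best_dev = n, dev
    if best_dev < tol.theta_tol:
        return f"H{best_n}"
    return "SH"


# ---------------------------------------------------------------------------
# point-group perception
# ---------------------------------------------------------------------------

@dataclass
class PointGroup:
    """A finite rotation group permuting the repeats."""

    family: str            # C, D, T, O or I
    order: int             # n of Cn/Dn; group order for T/O/I
    group_size: int        # number of elements including identity
    rotations: list        # (3,3) rotation matrices about the global centroid
    permutations: list     # repeat permutations, parallel to ``rotations``
    rmsd: float            # worst verification RMSD among the elements

    @property
    def label(self) -> str:
        if self.family in ("T", "O", "I"):
            return self.family
        return f"{self.family}{self.order}"


def uniform_rotation_grid(resolution_deg: float) -> np.ndarray:
    """Near-uniform deterministic sample of SO(3) as rotation matrices.

    Uses the super-Fibonacci quaternion spiral; the sample count is chosen so
    neighbouring rotations differ by roughly ``resolution_deg``.
    """
    res = np.radians(resolution_deg)
    n = max(500, int(8.0 * np.pi**2 / res**3))
    i = np.arange(n) + 0.5
    phi = np.sqrt(2.0)
    psi = 1.533751168755204288118041
    r = np.sqrt(i / n)
    R = np.sqrt(1.0 - i / n)
    alpha = 2.0 * np.pi * i / phi
    beta = 2.0 * np.pi * i / psi
    quat = np.stack(
        [r * np.sin(alpha), r * np.cos(alpha), R * np.sin(beta), R * np.cos(beta)],
        axis=1,
    )
    return Rotation.from_quat(quat).as_matrix()


def _rotation_only_superpose(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, float]:
    """Best pure rotation (about the origin) taking P onto Q, with RMSD."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1))))
    return R, rmsd


def _verify_permutation(
    perm: tuple[int, ...],
    repeat_coords: list[np.ndarray],
    centroid: np.ndarray,
    rmsd_threshold: float,
) -> tuple[np.ndarray, float] | None:
    """Refine and verify a candidate repeat permutation on all Ca atoms."""
    P = np.concatenate([repeat_coords[r] for r in range(len(perm))]) - centroid
    Q = np.concatenate([repeat_coords[perm[r]] for r in range(len(perm))]) - centroid
    R, rmsd = _rotation_only_superpose(P, Q)
    if rmsd < rmsd_threshold:
        return R, rmsd
    return None


def _compose_perm(a: tuple[int, ...], b: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(a[b[i]] for i in range(len(a)))


def detect_point_group(
    repeat_traces: list[np.ndarray],
    rmsd_threshold: float = 5.0,
    grid_deg: float = 16.0,
) -> PointGroup:
    """Perceive the point group of a set of equal-length repeat coordinate sets.

    Candidate rotations from a quaternion orientation grid are screened on the
    repeat centroids (must permute centroids onto centroids within the RMSD
    threshold), verified on all Ca atoms, and the surviving operations are
    closed under composition.  Returns a C1 group when no non-identity
    operation validates.
    """
    k = len(repeat_traces)
    if k < 2:
        return PointGroup("C", 1, 1, [np.eye(3)], [tuple(range(k))], 0.0)
    lengths = {len(tr) for tr in repeat_traces}
    if len(lengths) != 1:
        raise ValueError("repeat traces must have equal length (aligned columns)")
    coords = [np.asarray(tr, dtype=float) for tr in repeat_traces]
    centroids = np.array([c.mean(axis=0) for c in coords])
    center = centroids.mean(axis=0)
    cen = centroids - center

    # screen the orientation grid on centroids
    grid = uniform_rotation_grid(grid_deg)
    rotated = np.einsum("gij,kj->gki", grid, cen)          # (G, k, 3)
    diff = rotated[:, :, None, :] - cen[None, None, :, :]   # (G, k, k, 3)
    dist = np.linalg.norm(diff, axis=-1)                    # (G, k, k)
    nearest = dist.argmin(axis=2)                           # (G, k)
    nearest_d = dist.min(axis=2)
    cand_perms: set[tuple[int, ...]] = set()
    identity = tuple(range(k))
    screen = max(rmsd_threshold, 0.51 * float(np.median(np.linalg.norm(cen, axis=1))))
    for g in range(len(grid)):
        perm = tuple(int(x) for x in nearest[g])
        if perm == identity or len(set(perm)) != k:
            continue
        if float(np.sqrt(np.mean(nearest_d[g] ** 2))) > screen:
            continue
        cand_perms.add(perm)

    valid: dict[tuple[int, ...], tuple[np.ndarray, float]] = {identity: (np.eye(3), 0.0)}
    for perm in sorted(cand_perms):
        res = _verify_permutation(perm, coords, center, rmsd_threshold)
        if res is not None:
            valid[perm] = res

    # close under composition; test newly generated permutations directly
    tested = set(valid) | set(cand_perms)
    changed = True
    while changed:
        changed = False
        for a, b in itertools.product(list(valid), list(valid)):
            c = _compose_perm(a, b)
            if c in valid:
                continue
            if c not in tested:
                tested.add(c)
                res = _verify_permutation(c, coords, center, rmsd_threshold)
                if res is not None:
                    valid[c] = res
                    changed = True

    perms = sorted(valid)
    rots = [valid[p][0] for p in perms]
    worst = max(valid[p][1] for p in perms)
    g = len(perms)
    if g == 1:
        return PointGroup("C", 1, 1, rots, perms, worst)

    # characterize the group by its rotation axes
    axes, folds = [], []
    for p in perms:
        if p == identity:
            continue
        R = valid[p][0]
        rotvec = Rotation.from_matrix(R).as_rotvec()
        ang = np.linalg.norm(rotvec)
        axes.append(rotvec / ang)
        folds.append(max(2, int(round(2.0 * np.pi / ang))))
    axes = np.array(axes)
    folds = np.array(folds)

    def parallel(u, v, tol_deg=7.5):
        return abs(np.dot(u, v)) > np.cos(np.radians(tol_deg))

    # all axes parallel -> cyclic
    if all(parallel(axes[0], a) for a in axes[1:]):
        return PointGroup("C", g, g, rots, perms, worst)
    n_max = int(folds.max())
    # dihedral: a principal n-fold plus n perpendicular 2-folds, group size 2n
    for idx in np.flatnonzero(folds == n_max):
        principal = axes[idx]
        perp_twofold = sum(
            1
            for a, f in zip(axes, folds)
            if f == 2 and abs(np.dot(a, principal)) < np.sin(np.radians(10.0))
        )
        if g == 2 * n_max and perp_twofold >= n_max:
            return PointGroup("D", n_max, g, rots, perms, worst)
    if g == 12:
        return PointGroup("T", 12, g, rots, perms, worst)
    if g == 24:
        return PointGroup("O", 24, g, rots, perms, worst)
    if g == 60:
        return PointGroup("I", 60, g, rots, perms, worst)
    return PointGroup("C", n_max, g, rots, perms, worst)


# ---------------------------------------------------------------------------
# combining axes across recursion levels
# ---------------------------------------------------------------------------

def _line_distance(a1: np.ndarray, d1: np.ndarray, a2: np.ndarray, d2: np.ndarray) -> float:
    """Distance between two (near-)parallel or skew lines."""
    cross = np.cross(d1, d2)
    n = np.linalg.norm(cross)
    if n < 1e-6:  # parallel: distance from a2 to line 1
        v = a2 - a1
        return float(np.linalg.norm(v - np.dot(v, d1) * d1))
    return float(abs(np.dot(a2 - a1, cross / n)))


def combine_axes(
    levels: list[tuple[str, SymmetryAxis]],
    tol: GeometryTolerances = GeometryTolerances(),
) -> str:
    """Combine per-level labels/axes into an overall symmetry label.

    Collinear rotational axes multiply into a single higher-order Cn; an
    n-fold with an orthogonal 2-fold combines into Dn; anything else stays a
    hierarchical list joined with '/'.
    """
    if not levels:
        return "C1"
    merged: list[tuple[str, SymmetryAxis, int]] = []
    for label, axis in levels:
        order = int(label[1:]) if label[0] == "C" and label[1:].isdigit() else 0
        placed = False
        for i, (mlabel, maxis, morder) in enumerate(merged):
            if order == 0 or morder == 0:
                continue
            ang = np.degrees(
                np.arccos(np.clip(abs(np.dot(axis.direction, maxis.direction)), 0, 1))
            )
            dist = _line_distance(maxis.point, maxis.direction, axis.point, axis.direction)
            if ang < tol.axis_angle_tol and dist < tol.axis_dist_tol:
                new_order = morder * order
                merged[i] = (f"C{new_order}", maxis, new_order)
                placed = True
                break
            if abs(ang - 90.0) < tol.axis_angle_tol and mlabel.startswith("C") and 2 in (order, morder):
                # an n-fold plus an orthogonal 2-fold forms a dihedral group
                n = morder if order == 2 else order
                principal = maxis if order == 2 else axis
                merged[i] = (f"D{n}", principal, n)
                placed = True
                break
        if not placed:
            merged.append((label, axis, order))
    return "/".join(m[0] for m in merged)
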