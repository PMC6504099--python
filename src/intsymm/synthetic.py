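"""Synthetic Ca structures with known symmetry ground truth.

The generator places copies of a seed motif (ideal alpha-helix, helix
hairpin, or strand pair) by powers of a symmetry operator — cyclic, dihedral,
helical (screw), translational or superhelical — joins them with short
linkers replicated by the same operator, and optionally perturbs every
coordinate with iid Gaussian noise.  Because the linkers are replicated
symmetrically, the noise-free chain is exactly symmetric except for the
missing trailing linker.  Asymmetric decoys are self-avoiding random Ca
walks with protein-like 3.8 A virtual bonds.

The returned ground truth records the true repeat ranges (trace indices of
the motif copies), the generating operator and its screw axis, and the
symmetry-type label, so every pipeline stage can be tested against a known
answer without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import RigidTransform, SymmetryAxis, axis_from_transform
from .structure_io import CoordinateTrace, Residue, ResidueLabel, Structure

# standard alpha-helix Ca geometry
HELIX_RISE = 1.5      # A per residue
HELIX_TWIST = 100.0   # deg per residue
HELIX_RADIUS = 2.3    # A


# ---------------------------------------------------------------------------
# motifs
# ---------------------------------------------------------------------------

def ideal_helix(n_res: int) -> np.ndarray:
    """Ca coordinates of an ideal alpha-helix along +z starting at the origin."""
    i = np.arange(n_res)
    ang = np.radians(HELIX_TWIST * i)
    return np.stack(
        [HELIX_RADIUS * np.cos(ang), HELIX_RADIUS * np.sin(ang), HELIX_RISE * i],
        axis=1,
    )


def _bridge(a: np.ndarray, b: np.ndarray, n: int, bow: float = 1.5) -> np.ndarray:
    """n points joining a to b (exclusive) along a gently bowed path."""
    if n <= 0:
        return np.zeros((0, 3))
    ts = (np.arange(n) + 1.0) / (n + 1.0)
    line = a[None, :] + ts[:, None] * (b - a)[None, :]
    # bow perpendicular to the chord so the linker is not collinear
    chord = b - a
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(chord, ref)) > 0.9 * np.linalg.norm(chord):
        ref = np.array([1.0, 0.0, 0.0])
    perp = np.cross(chord, ref)
    norm = np.linalg.norm(perp)
    if norm > 1e-9:
        perp = perp / norm
        line = line + bow * np.sin(np.pi * ts)[:, None] * perp[None, :]
    return line


def helix_hairpin(n_res: int) -> np.ndarray:
    """Two antiparallel ideal helices joined by a 3-residue turn (>= 2 SSEs).

    The arms are deliberately unequal (62/38 split) so the motif itself is
    asymmetric: a repeating unit must not contain an internal 2-fold of its
    own, or it would not be an asymmetric repeating unit.
    """
    n_turn = 3
    n1 = int(round(0.62 * (n_res - n_turn)))
    n2 = n_res - n_turn - n1
    h1 = ideal_helix(n1)
    h2 = ideal_helix(n2)
    # flip the second helix to run downward and offset it sideways
    flip = Rotation.from_euler("x", 180, degrees=True).as_matrix()
    h2 = h2 @ flip.T
    h2 = h2 + np.array([9.0, 0.0, h1[-1, 2] + 1.0])
    turn = _bridge(h1[-1], h2[0], n_turn)
    return np.concatenate([h1, turn, h2])


def strand_pair(n_res: int) -> np.ndarray:
    """Two antiparallel extended strands joined by a 2-residue turn.

    Unequal arms, for the same reason as the helix hairpin."""
    n_turn = 2
    n1 = int(round(0.62 * (n_res - n_turn)))
    n2 = n_res - n_turn - n1

    def strand(n):
        i = np.arange(n)
        return np.stack(
            [np.zeros(n), 0.9 * (-1.0) ** i, 3.4 * i], axis=1
        )

    s1 = strand(n1)
    s2 = strand(n2)
    flip = Rotation.from_euler("x", 180, degrees=True).as_matrix()
    s2 = s2 @ flip.T + np.array([4.8, 0.0, s1[-1, 2] + 1.0])
    turn = _bridge(s1[-1], s2[0], n_turn, bow=1.0)
    return np.concatenate([s1, turn, s2])


def helix_strand_motif(n_res: int) -> np.ndarray:
    """An alpha+beta motif: one helix followed by a small beta hairpin.

    This is the default repeat unit for symmetric fixtures because it is
    genuinely asymmetric: unlike a helix hairpin, whose two arms superimpose
    onto each other (any two alpha-helices do), a helix never aligns onto a
    strand, so the motif contains no internal symmetry of its own.
    """
    n_bridge = 2
    n_h = max(8, int(round(0.5 * n_res)))
    sp = strand_pair(n_res - n_h - n_bridge)
    h = ideal_helix(n_h)
    flip = Rotation.from_euler("x", 180, degrees=True).as_matrix()
    sp = sp @ flip.T
    sp = sp - sp[0] + h[-1] + np.array([6.5, 0.0, 1.0])
    bridge = _bridge(h[-1], sp[0], n_bridge)
    return np.concatenate([h, bridge, sp])


_MOTIFS = {
    "helix": ideal_helix,
    "hairpin": helix_hairpin,
    "strands": strand_pair,
    "mixed": helix_strand_motif,
}


# ---------------------------------------------------------------------------
# generator spec and ground truth
# ---------------------------------------------------------------------------

@dataclass
class GeneratorSpec:
    """Recipe for one synthetic symmetric structure.

    arrangement is one of cyclic, dihedral, helical, translational,
    superhelical; theta/rise apply to helical and superhelical, shift to
    translational, precession to superhelical.  radius=None picks a
    clash-free radius automatically.
    """

    motif: str = "mixed"            # or "helix", "hairpin", "strands", coords
    motif_len: int = 24
    n_repeats: int = 4
    arrangement: str = "cyclic"
    radius: float | None = None
    theta: float = 120.0            # deg, helical/superhelical twist per repeat
    rise: float = 5.0               # A, helical rise per repeat
    shift: float = 12.0             # A, translational shift per repeat
    precession: float = 30.0        # deg, superhelical axis precession
    noise_sigma: float = 0.0
    linker_len: int = 3
    seed: int = 0
    motif_coords: np.ndarray | None = None


@dataclass
class GroundTruth:
    label: str
    repeat_ranges: list            # [(start, end)] inclusive trace indices per repeat
    operator: RigidTransform       # maps repeat r onto repeat r+1
    axis: SymmetryAxis
    coords: np.ndarray             # the exact generated Ca coordinates
    extra_axes: list = field(default_factory=list)  # e.g. dihedral 2-fold


def _structure_from_coords(coords: np.ndarray, source_id: str) -> Structure:
    residues = [
        Residue(ResidueLabel("A", i + 1, "", "ALA"), {"CA": coords[i]})
        for i in range(len(coords))
    ]
    return Structure(source_id=source_id, residues=residues)


def _auto_radius(motif: np.ndarray, n: int, minimum: float = 10.0) -> float:
    xy = motif[:, :2] - motif[:, :2].mean(axis=0)
    extent = float(np.max(np.linalg.norm(xy, axis=1)))
    need = (2.0 * extent + 4.0) / (2.0 * np.sin(np.pi / max(n, 2)))
    return max(minimum, need)


def _min_inter_repeat_distance(coords: np.ndarray, ranges: list) -> float:
    best = np.inf
    for a in range(len(ranges)):
        for b in range(a + 1, len(ranges)):
            xa = coords[ranges[a][0]: ranges[a][1] + 1]
            xb = coords[ranges[b][0]: ranges[b][1] + 1]
            d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=-1)
            best = min(best, float(d.min()))
    return best


def _operator(spec: GeneratorSpec, n: int) -> tuple[RigidTransform, str]:
    """The repeat r -> r+1 operator of the arrangement and the truth label."""
    if spec.arrangement == "cyclic":
        R = Rotation.from_euler("z", 360.0 / n, degrees=True).as_matrix()
        return RigidTransform(R, np.zeros(3)), f"C{n}"
    if spec.arrangement == "helical":
        R = Rotation.from_euler("z", spec.theta, degrees=True).as_matrix()
        label = f"H{int(round(360.0 / spec.theta))}"
        return RigidTransform(R, np.array([0.0, 0.0, spec.rise])), label
    if spec.arrangement == "translational":
        # shift along y, where the standard motifs are narrow, to avoid clashes
        return RigidTransform(np.eye(3), np.array([0.0, spec.shift, 0.0])), "R"
    raise ValueError(f"unknown arrangement {spec.arrangement!r}")


def make_symmetric(spec: GeneratorSpec) -> tuple[Structure, GroundTruth]:
    """Generate a symmetric Ca structure plus its ground truth.

    Copies of the motif are placed by powers of the arrangement operator and
    joined with linkers replicated by the same operator.  If any two repeats
    clash (inter-repeat Ca distance < 2 A) the structure is regenerated at a
    larger radius.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.motif_coords is not None:
        motif = np.asarray(spec.motif_coords, dtype=float)
    else:
        motif = _MOTIFS[spec.motif](spec.motif_len)
    if spec.arrangement == "dihedral":
        return _make_dihedral(spec, motif, rng)
    if spec.arrangement == "superhelical":
        return _make_superhelical(spec, motif, rng)

    n = spec.n_repeats
    op, label = _operator(spec, n)
    radius = spec.radius if spec.radius is not None else _auto_radius(motif, n)
    if spec.arrangement == "translational":
        radius = 0.0 if spec.radius is None else radius

    for _attempt in range(6):
        base = motif + np.array([radius, 0.0, 0.0])
        pieces, ranges = [], []
        pos = 0
        for r in range(n):
            T = op.power(r)
            rep = T.apply(base)
            pieces.append(rep)
            ranges.append((pos, pos + len(rep) - 1))
            pos += len(rep)
            if r < n - 1 and spec.linker_len > 0:
                nxt_start = op.power(r + 1).apply(base[:1])[0]
                link = _bridge(rep[-1], nxt_start, spec.linker_len)
                pieces.append(link)
                pos += len(link)
        coords = np.concatenate(pieces)
        if _min_inter_repeat_distance(coords, ranges) >= 2.0 or spec.arrangement != "cyclic":
            break
        radius *= 1.3
    if spec.noise_sigma > 0:
        coords = coords + rng.normal(0.0, spec.noise_sigma, coords.shape)
    axis = axis_from_transform(op)
    truth = GroundTruth(label, ranges, op, axis, coords.copy())
    return _structure_from_coords(coords, f"synth_{label}_{spec.seed}"), truth


def _make_dihedral(spec, motif, rng):
    """Dn arrangement: n repeats by the z n-fold, then their images under the
    x 2-fold, in chain order A0..A(n-1) B0..B(n-1)."""
    n = spec.n_repeats
    radius = spec.radius if spec.radius is not None else _auto_radius(motif, n)
    zrot = RigidTransform(
        Rotation.from_euler("z", 360.0 / n, degrees=True).as_matrix(), np.zeros(3)
    )
    xflip = RigidTransform(
        Rotation.from_euler("x", 180, degrees=True).as_matrix(), np.zeros(3)
    )
    height = 0.6 * (motif[:, 2].max() - motif[:, 2].min()) + 3.0
    for _attempt in range(6):
        base = motif + np.array([radius, 0.0, height])
        reps = [zrot.power(r).apply(base) for r in range(n)]
        reps += [xflip.apply(x) for x in reps[:n]]
        pieces, ranges = [], []
        pos = 0
        for r, rep in enumerate(reps):
            pieces.append(rep)
            ranges.append((pos, pos + len(rep) - 1))
            pos += len(rep)
            if r < len(reps) - 1 and spec.linker_len > 0:
                link = _bridge(rep[-1], reps[r + 1][0], spec.linker_len)
                pieces.append(link)
                pos += len(link)
        coords = np.concatenate(pieces)
        if _min_inter_repeat_distance(coords, ranges) >= 2.0:
            break
        radius *= 1.3
    if spec.noise_sigma > 0:
        coords = coords + rng.normal(0.0, spec.noise_sigma, coords.shape)
    truth = GroundTruth(
        f"D{n}", ranges, zrot, axis_from_transform(zrot), coords.copy(),
        extra_axes=[axis_from_transform(xflip)],
    )
    return _structure_from_coords(coords, f"synth_D{n}_{spec.seed}"), truth


def _make_superhelical(spec, motif, rng):
    """Superhelical arrangement: the local screw axis precesses per repeat, so
    no single fixed operator relates each repeat to the next."""
    n = spec.n_repeats
    radius = spec.radius if spec.radius is not None else _auto_radius(motif, n)
    base = motif + np.array([radius, 0.0, 0.0])
    screw = RigidTransform(
        Rotation.from_euler("z", spec.theta, degrees=True).as_matrix(),
        np.array([0.0, 0.0, spec.rise]),
    )
    prec = RigidTransform(
        Rotation.from_euler("x", spec.precession, degrees=True).as_matrix(), np.zeros(3)
    )
    pieces, ranges = [], []
    T = RigidTransform.identity()
    pos = 0
    for r in range(n):
        rep = T.apply(base)
        pieces.append(rep)
        ranges.append((pos, pos + len(rep) - 1))
        pos += len(rep)
        T = T.compose(prec.compose(screw))
        if r < n - 1 and spec.linker_len > 0:
            nxt = T.apply(base[:1])[0]
            link = _bridge(rep[-1], nxt, spec.linker_len)
            pieces.append(link)
            pos += len(link)
    coords = np.concatenate(pieces)
    if spec.noise_sigma > 0:
        coords = coords + rng.normal(0.0, spec.noise_sigma, coords.shape)
    truth = GroundTruth("SH", ranges, screw, axis_from_transform(screw), coords.copy())
    return _structure_from_coords(coords, f"synth_SH_{spec.seed}"), truth


# ---------------------------------------------------------------------------
# decoys
# ---------------------------------------------------------------------------

def make_decoy(n_res: int, seed: int = 0) -> Structure:
    """Self-avoiding random Ca walk with 3.8 A virtual bonds and no designed
    symmetry (false-positive control)."""
    if n_res < 30:
        raise ValueError("decoys need at least 30 residues")
    rng = np.random.default_rng(seed)
    for _restart in range(100):
        pts = [np.zeros(3)]
        direction = _random_unit(rng)
        pts.append(pts[0] + 3.8 * direction)
        ok = True
        while len(pts) < n_res:
            for _try in range(120):
                # protein-like virtual bond angle between ~70 and ~140 deg
                ang = np.radians(rng.uniform(70.0, 140.0))
                axis = _random_unit(rng)
                axis = axis - np.dot(axis, direction) * direction
                nrm = np.linalg.norm(axis)
                if nrm < 1e-6:
                    continue
                axis /= nrm
                newdir = np.cos(np.pi - ang) * direction + np.sin(np.pi - ang) * axis
                newdir /= np.linalg.norm(newdir)
                bond = 3.8 + rng.normal(0.0, 0.03)
                cand = pts[-1] + bond * newdir
                prev = np.array(pts[:-1])
                if len(prev) and np.min(np.linalg.norm(prev - cand, axis=1)) < 4.0:
                    continue
                pts.append(cand)
                direction = newdir
                break
            else:
                ok = False
                break
        if ok:
            return _structure_from_coords(np.array(pts), f"decoy_{seed}")
    raise RuntimeError("could not generate a self-avoiding walk")


def write_fixture(spec: GeneratorSpec, pdb_path, truth_path=None):
    """Generate a symmetric fixture, write it as PDB with a JSON ground-truth
    sidecar, and return (structure, truth)."""
    import json

    from .structure_io import write_pdb

    structure, truth = make_symmetric(spec)
    write_pdb(structure, pdb_path)
    if truth_path is not None:
        payload = {
            "label": truth.label,
            "repeat_ranges": [list(r) for r in truth.repeat_ranges],
            "axis": {
                "direction": [float(x) for x in truth.axis.direction],
                "point": [float(x) for x in truth.axis.point],
                "theta_deg": truth.axis.theta_deg,
                "screw_t": truth.axis.screw_t,
            },
            "arrangement": spec.arrangement,
            "n_repeats": spec.n_repeats,
            "motif": spec.motif,
            "motif_len": spec.motif_len,
            "noise_sigma": spec.noise_sigma,
            "seed": spec.seed,
        }
        with open(truth_path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
    return structure, truth


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def trace_of(structure: Structure) -> CoordinateTrace:
    """Convenience: the Ca trace of a generated structure."""
    from .structure_io import extract_ca_trace

    return extract_ca_trace(structure)
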