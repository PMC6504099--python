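"""Structural self-alignment of a Ca trace, supporting circular permutation.

The trace is aligned against itself with a combinatorial-extension style
procedure: a similarity matrix of aligned fragment pairs (window 8) compares
intra-fragment Ca-Ca distance patterns; a band of half-width one window
around the identity diagonal is masked out so the trivial alignment is
excluded; and the optimal path is searched against a duplicated copy of the
trace so that it may wrap the C-terminus into the N-terminus (a circular
permutation, diagnostic of closed symmetry).  The path search itself is a
local affine-gap dynamic program (biotite's C implementation with a custom
position-specific substitution matrix).  The resulting residue mapping is
superimposed and scored with TM-score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from biotite.sequence import Alphabet, GeneralSequence
from biotite.sequence.align import SubstitutionMatrix, align_optimal
from scipy.spatial.distance import cdist

from .errors import TooShortError
from .geometry import RigidTransform, superimpose
from .params import ScoringParams, d0_from_length
from .structure_io import CoordinateTrace

_MASK_SCORE = -1.0e4  # A-units; forbids paths through the identity band
_SCALE = 100.0        # score quantization for the integer DP


@dataclass
class SelfAlignment:
    """A partial injective non-identity mapping of trace positions onto trace
    positions, with its rigid superposition and TM-score."""

    mapping: dict           # position -> position, f(i) != i, injective
    transform: RigidTransform
    tm_score: float
    rmsd: float
    has_cp: bool
    n: int                  # trace length

    @property
    def n_aligned(self) -> int:
        return len(self.mapping)

    def pairs(self) -> list:
        return sorted(self.mapping.items())


def _fragment_scores(X: np.ndarray, window: int, frag_cutoff: float) -> np.ndarray:
    """Residue-level match scores from fragment distance-pattern similarity.

    Score(i, j) = frag_cutoff - mean |d(i+a, i+b) - d(j+a, j+b)| over residue
    pairs (a < b) inside the window, where j indexes the duplicated trace.
    """
    n = len(X)
    dup = np.concatenate([X, X])
    D1 = cdist(X, X)
    D2 = cdist(dup, dup)
    ni = n - window + 1
    nj = 2 * n - window + 1
    F = np.zeros((ni, nj))
    npairs = 0
    for a in range(window):
        for b in range(a + 1, window):
            v1 = np.array([D1[i + a, i + b] for i in range(ni)])
            v2 = np.array([D2[j + a, j + b] for j in range(nj)])
            F += np.abs(v1[:, None] - v2[None, :])
            npairs += 1
    F /= npairs
    # extend fragment-start scores to all residues (clip edge windows)
    ii = np.minimum(np.arange(n), ni - 1)
    jj = np.minimum(np.arange(2 * n), nj - 1)
    return frag_cutoff - F[np.ix_(ii, jj)]


def _identity_mask(n: int, window: int) -> np.ndarray:
    """Boolean (n, 2n) mask of the identity band: circular sequence offset
    smaller than one window."""
    i = np.arange(n)[:, None]
    j = np.arange(2 * n)[None, :]
    mod = (j - i) % n
    circ = np.minimum(mod, n - mod)
    return circ < window


def tm_superpose(
    P: np.ndarray, Q: np.ndarray, normalization_length: int
) -> tuple[float, RigidTransform]:
    """Maximize TM-score of the paired point sets over rigid superpositions.

    Standard TM-score search: seed superpositions on sliding sub-windows of
    the pair list, then iteratively re-superimpose on the pairs within a
    distance cutoff until the selection is stable; the score is evaluated
    over all pairs and the best superposition is kept.
    """
    L = len(P)
    d0 = d0_from_length(normalization_length)
    if L == 0:
        return 0.0, RigidTransform.identity()

    def tm_of(T: RigidTransform) -> float:
        d = np.linalg.norm(T.apply(P) - Q, axis=1)
        return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / normalization_length)

    best_tm, best_T = -1.0, RigidTransform.identity()
    sizes = sorted({L, max(4, L // 2), max(4, L // 4)}, reverse=True)
    for size in sizes:
        if size > L:
            continue
        step = max(1, size // 2)
        for start in range(0, L - size + 1, step):
            sel = np.arange(start, start + size)
            prev_sel = None
            try:
                T, _ = superimpose(P[sel], Q[sel])
            except Exception:
                continue
            for _it in range(30):
                tm = tm_of(T)
                if tm > best_tm:
                    best_tm, best_T = tm, T
                d = np.linalg.norm(T.apply(P) - Q, axis=1)
                cut = max(d0 + 1.0, 3.5)
                sel_new = np.flatnonzero(d < cut)
                while len(sel_new) < 3 and cut < 30.0:
                    cut += 1.0
                    sel_new = np.flatnonzero(d < cut)
                if len(sel_new) < 3:
                    break
                if prev_sel is not None and np.array_equal(sel_new, prev_sel):
                    break
                prev_sel = sel_new
                try:
                    T, _ = superimpose(P[sel_new], Q[sel_new])
                except Exception:
                    break
    return max(best_tm, 0.0), best_T


def tm_score(mapping: dict, trace: CoordinateTrace, normalization_length: int) -> float:
    """TM = (1/L_n) sum_i 1/(1 + (d_i/d0)^2) over mapped pairs, maximized over
    the standard superposition search."""
    if not mapping:
        return 0.0
    idx = sorted(mapping)
    P = trace.coords[idx]
    Q = trace.coords[[mapping[i] for i in idx]]
    tm, _ = tm_superpose(P, Q, normalization_length)
    return tm


def _candidate_offsets(S: np.ndarray, n: int, w: int, k: int = 8) -> list:
    """Diagonal offsets with the highest positive similarity mass.

    A consistent rigid self-alignment runs close to one diagonal of the
    (query x duplicated-query) matrix; candidates are local maxima of the
    per-diagonal positive score, with non-maximum suppression of one window.
    """
    pos = np.clip(S, 0.0, None)
    diag_mass = np.array(
        [pos.diagonal(offset=c).sum() for c in range(w, 2 * n - 2 * w + 1)]
    )
    offsets = []
    mass = diag_mass.copy()
    for _ in range(k):
        c = int(np.argmax(mass))
        if mass[c] <= 0.0:
            break
        offsets.append(c + w)
        lo, hi = max(0, c - w), min(len(mass), c + w + 1)
        mass[lo:hi] = -1.0
    return offsets


def _path_for_band(submats, seqs, mat, gap, c: int, band: int, n: int):
    """Best local path restricted to the band |j - i - c| <= band."""
    banded = mat.copy()
    i = np.arange(n)[:, None]
    j = np.arange(2 * n)[None, :]
    banded[np.abs(j - i - c) > band] = int(_MASK_SCORE * _SCALE)
    alph1, alph2 = submats
    seq1, seq2 = seqs
    submat = SubstitutionMatrix(alph1, alph2, banded)
    alns = align_optimal(seq1, seq2, submat, gap_penalty=gap, local=True, max_number=1)
    return [(int(a), int(b)) for a, b in alns[0].trace if a != -1 and b != -1]


def _mapping_from_pairs(pairs, n: int) -> dict:
    """Reduce duplicated-copy path pairs to an injective non-identity map."""
    mapping: dict[int, int] = {}
    used: set[int] = set()
    for i, j in pairs:
        jm = j % n
        if jm == i or jm in used or i in mapping:
            continue
        mapping[i] = jm
        used.add(jm)
    return mapping


def _distance_dp_mapping(
    X: np.ndarray, T: RigidTransform, n: int, w: int, gap, seqs, alphs,
    dist_cutoff: float = 8.0,
) -> dict:
    """Re-derive the residue mapping from superposition distances.

    Given a rigid transform, score cell (i, j) by how close T(x_i) lands to
    x_{j mod n} and run the gapped path search again.  Because the score is
    tied to one transform, the path cannot mix different symmetry operations,
    and edge effects of the fragment windows disappear.
    """
    TX = T.apply(X)
    d = cdist(TX, X)
    M = dist_cutoff - np.concatenate([d, d], axis=1)  # (n, 2n)
    M[_identity_mask(n, w)] = _MASK_SCORE
    M[np.tril_indices(n)] = _MASK_SCORE
    mat = np.round(M * _SCALE).astype(np.int32)
    submat = SubstitutionMatrix(alphs[0], alphs[1], mat)
    alns = align_optimal(seqs[0], seqs[1], submat, gap_penalty=gap, local=True, max_number=1)
    pairs = [(int(a), int(b)) for a, b in alns[0].trace if a != -1 and b != -1]
    return _mapping_from_pairs(pairs, n)


def self_align(trace: CoordinateTrace, params: ScoringParams = ScoringParams()) -> SelfAlignment:
    """Optimal non-identity structural self-alignment of the trace.

    The fragment-similarity path search is run once per candidate diagonal,
    banded so that a single path cannot mix different symmetry operations
    (e.g. jump from the one-repeat to the two-repeat diagonal).  Each
    candidate mapping is refined by iterative superposition plus a
    superposition-distance path search, and the highest-TM-score mapping
    wins; ties go to the longer alignment, then the smaller start position.
    Returns a degenerate alignment (empty mapping, TM 0) when no path of at
    least two windows of aligned positions exists.
    """
    n = len(trace)
    w = params.window
    if n < 2 * w:
        raise TooShortError(f"trace length {n} < 2 x window ({2 * w})")
    X = trace.coords

    S = _fragment_scores(X, w, params.frag_cutoff)
    S[_identity_mask(n, w)] = _MASK_SCORE
    # orient paths forward: the mapping sends each position to a later one
    # (modulo wrap through the duplicated copy)
    S[np.tril_indices(n)] = _MASK_SCORE
    mat = np.round(S * _SCALE).astype(np.int32)

    alphs = (Alphabet(list(range(n))), Alphabet(list(range(2 * n))))
    seqs = (
        GeneralSequence(alphs[0], list(range(n))),
        GeneralSequence(alphs[1], list(range(2 * n))),
    )
    gap = (-int(params.gap_open * _SCALE), -int(params.gap_extend * _SCALE))
    band = 2 * w

    best = None  # (key, mapping, T, rmsd)
    for c in _candidate_offsets(S, n, w):
        pairs = _path_for_band(alphs, seqs, mat, gap, c, band, n)
        mapping = _mapping_from_pairs(pairs, n)
        if len(mapping) < 2 * w:
            continue
        tm, T = _score_mapping(mapping, X, n)
        # refine: superposition-distance path search, re-superpose, repeat
        for _it in range(2):
            refined = _distance_dp_mapping(X, T, n, w, gap, seqs, alphs)
            if len(refined) < 2 * w:
                break
            tm2, T2 = _score_mapping(refined, X, n)
            if tm2 <= tm:
                break
            mapping, tm, T = refined, tm2, T2
        idx = sorted(mapping)
        P, Q = X[idx], X[[mapping[i] for i in idx]]
        rmsd = float(np.sqrt(np.mean(np.sum((T.apply(P) - Q) ** 2, axis=1))))
        key = (round(tm, 6), len(mapping), -idx[0])
        if best is None or key > best[0]:
            best = (key, mapping, T, rmsd)

    if best is None:
        return SelfAlignment({}, RigidTransform.identity(), 0.0, 0.0, False, n)
    key, mapping, T, rmsd = best
    aln = SelfAlignment(mapping, T, key[0], rmsd, False, n)
    aln.has_cp = detect_circular_permutation(aln)
    return aln


def _score_mapping(mapping: dict, X: np.ndarray, n: int) -> tuple[float, RigidTransform]:
    idx = sorted(mapping)
    return tm_superpose(X[idx], X[[mapping[i] for i in idx]], n)


def detect_circular_permutation(aln: SelfAlignment) -> bool:
    """True iff the mapping is not order-preserving on 0..n-1, i.e. the
    alignment path wrapped the C-terminus into the N-terminus.

    The wrap shows as a single large backward jump (about -n) in the image
    sequence followed by a real aligned segment; isolated small descents from
    local alignment noise do not count.
    """
    if not aln.mapping:
        return False
    images = [aln.mapping[i] for i in sorted(aln.mapping)]
    n = aln.n
    for pos, (a, b) in enumerate(zip(images, images[1:])):
        if b - a < -n / 2 and len(images) - (pos + 1) >= 4:
            return True
    return False
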