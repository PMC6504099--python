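"""Parameter containers for all pipeline stages.

Every tunable threshold of the method lives here so the engine, the CLI and
the tests share one source of defaults.  Distances are in Angstrom, angles in
degrees unless noted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


def d0_from_length(n: int) -> float:
    """TM-score distance scale d0 = 1.24*(L-15)^(1/3) - 1.8, floored at 0.5 A."""
    return float(max(0.5, 1.24 * np.cbrt(n - 15.0) - 1.8))


@dataclass(frozen=True)
class ScoringParams:
    """Parameters of the CE-style self-alignment and TM scoring.

    window
        Fragment length for the CE similarity matrix (aligned fragment pairs).
    frag_cutoff
        Fragment dissimilarity (average absolute difference of intra-fragment
        Ca-Ca distances, A) at which the match score crosses zero.
    gap_open, gap_extend
        Linear/affine gap penalties of the path search, in the same units as
        the match score (A of fragment dissimilarity).
    max_gap
        Maximum number of consecutive gap steps allowed in the path search.
    """

    window: int = 8
    frag_cutoff: float = 4.0
    gap_open: float = 6.0
    gap_extend: float = 0.6
    max_gap: int = 30

    def d0(self, normalization_length: int) -> float:
        return d0_from_length(normalization_length)


@dataclass(frozen=True)
class McParams:
    """Monte Carlo optimization parameters.

    C is the maximum score of an alignment position; d_c the distance cutoff
    at which a position's score crosses zero; G the linear gap penalty
    (defaults to C/2); max_iter the iteration budget M (defaults to 100x the
    number of residues); the run stalls out after max_iter/stall_divisor
    consecutive rejected moves.  Shrink and gap moves pick their column/cell
    from a geometric distribution over the distance ranking.
    """

    C: float = 20.0
    d_c: float = 7.0
    G: float | None = None
    max_iter: int | None = None
    stall_divisor: int = 50
    geometric_p: float = 0.5
    move_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    min_columns: int = 3

    def gap_penalty(self) -> float:
        return self.C / 2.0 if self.G is None else self.G

    def iterations(self, n_residues: int) -> int:
        return 100 * n_residues if self.max_iter is None else self.max_iter


@dataclass(frozen=True)
class GeometryTolerances:
    """Tolerances of axis classification and point-group perception.

    t_tol/theta_tol decide when a screw translation/rotation counts as
    negligible; grid_deg is the target resolution of the quaternion
    orientation grid; rmsd_threshold validates a candidate symmetry rotation.
    """

    t_tol: float = 2.0
    theta_tol: float = 5.0
    axis_angle_tol: float = 5.0
    axis_dist_tol: float = 2.0
    rmsd_threshold: float = 5.0
    grid_deg: float = 16.0


@dataclass(frozen=True)
class OrderParams:
    """Order-detection parameters (shared by the three detectors)."""

    max_order: int = 8
    #: regularizer weight on k in the DeltaPosition objective
    alpha: float = 0.002
    #: DeltaPosition significance ceiling on mean circular displacement / n
    delta_ceiling: float = 0.1
    #: minimum fraction of nodes where f^k must be defined
    min_composition_coverage: float = 0.1
    #: RotationAngle acceptance tolerance (deg) and minimum angle (deg)
    angle_tol: float = 10.0
    min_angle: float = 5.0


@dataclass(frozen=True)
class RefineParams:
    max_offset: int = 3
    min_columns: int = 3


@dataclass(frozen=True)
class EngineParams:
    """Top-level engine parameters: significance thresholds and nested stage
    parameters."""

    tm_threshold: float = 0.4
    avg_tm_threshold: float = 0.36
    min_sse: int = 0
    min_sse_len: int = 4
    #: 0 means recurse until a non-significant level
    symm_levels: int = 0
    order_method: str = "auto"
    refine_method: str = "auto"
    optimize: bool = True
    seed: int = 0
    scoring: ScoringParams = field(default_factory=ScoringParams)
    order: OrderParams = field(default_factory=OrderParams)
    refine: RefineParams = field(default_factory=RefineParams)
    mc: McParams = field(default_factory=McParams)
    geometry: GeometryTolerances = field(default_factory=GeometryTolerances)

    def with_(self, **kwargs) -> "EngineParams":
        return replace(self, **kwargs)
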