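"""Exact 2D geometry of the circular tank and of pairwise fish configurations.

Conventions used throughout the package:

* coordinates are tank-centered Cartesian meters;
* angles are in radians, counterclockwise-positive, wrapped to (−π, π];
* the wall angle ``angle_to_normal`` (θ_W) is measured from the *outward*
  normal at the impact point to the fish heading, so θ_W = 0 means a head-on
  approach and |θ_W| → π/2 a grazing ray;
* the bearing ψ of a neighbor is measured from the focal fish's heading to
  the direction of the neighbor's position (positive = neighbor to the left);
* the relative heading φ is wrap(θ_j − θ_i).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError

__all__ = [
    "TankGeometry",
    "FishState",
    "WallStimulus",
    "PairStimulus",
    "NeighborGraph",
    "wrap_angle",
    "adjacency_matrix",
    "wall_impact",
    "wall_impact_arrays",
    "pair_stimuli",
    "pair_stimuli_arrays",
    "neighbor_graph",
]


def wrap_angle(a):
    """Wrap an angle (scalar or array) to the interval (−π, π]."""
    a = np.asarray(a, dtype=float)
    wrapped = -((-a + np.pi) % (2.0 * np.pi) - np.pi)
    return wrapped if wrapped.ndim else float(wrapped)


@dataclass
class TankGeometry:
    """Circular tank; ``bounded=False`` means open-space mode (no wall)."""

    radius: float = 2.0
    center: np.ndarray = field(default_factory=lambda: np.zeros(2))
    bounded: bool = True

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if not self.radius > 0:
            raise ValueError(f"tank radius must be > 0, got {self.radius}")

    def contains(self, position) -> bool:
        return float(np.hypot(*(np.asarray(position) - self.center))) < self.radius


@dataclass
class FishState:
    """Position, heading, angular velocity and speed of one agent at one instant."""

    position: np.ndarray
    heading: float
    omega: float = 0.0
    speed: float = 0.3

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.heading = wrap_angle(self.heading)
        if not self.speed > 0:
            raise ValueError(f"speed must be strictly positive, got {self.speed}")


@dataclass
class WallStimulus:
    """Wall-impact geometry: distance D_W, signed angle θ_W, time-to-impact D_W/v."""

    dist_to_impact: float
    angle_to_normal: float
    time_to_impact: float


@dataclass
class PairStimulus:
    """Pairwise stimulus (d_ij, ψ_ij, φ_ij) of a neighbor seen from a focal fish."""

    distance: float
    bearing: float
    heading_diff: float
    coincident: bool = False


class NeighborGraph:
    """Per-fish neighbor sets stored as a boolean adjacency matrix.

    ``method`` is one of ``"all"``, ``"voronoi_shell1"`` or ``"knn:K"``.
    """

    def __init__(self, adjacency: np.ndarray, method: str):
        adjacency = np.asarray(adjacency, dtype=bool)
        if adjacency.ndim != 2 or adjacency.shape[0] != adjacency.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if np.any(np.diag(adjacency)):
            raise ValueError("self-neighbors are not allowed")
        self.adjacency = adjacency
        self.method = method

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def counts(self) -> np.ndarray:
        """N_i, the number of neighbors of each fish."""
        return self.adjacency.sum(axis=1)

    def neighbors(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.adjacency[i])


# ---------------------------------------------------------------------------
# wall impact
# ---------------------------------------------------------------------------

def wall_impact_arrays(positions, headings, speeds, tank: TankGeometry):
    """Vectorized ray–circle wall impact for several fish at once.

    Returns ``(dist_to_impact, angle_to_normal, time_to_impact)`` arrays.
    The ray parameter is the positive root of |p + λh| = R.
    """
    if not tank.bounded:
        raise ValueError("wall impact is undefined for an unbounded (open-space) tank")
    p = np.asarray(positions, dtype=float) - tank.center
    headings = np.asarray(headings, dtype=float)
    speeds = np.asarray(speeds, dtype=float)
    r2 = np.einsum("ij,ij->i", p, p)
    if np.any(r2 >= tank.radius**2):
        raise ValueError("position on or outside the tank wall")
    h = np.stack([np.cos(headings), np.sin(headings)], axis=1)
    b = np.einsum("ij,ij->i", p, h)
    lam = -b + np.sqrt(b * b + tank.radius**2 - r2)
    q = p + lam[:, None] * h
    n = q / tank.radius
    cross = n[:, 0] * h[:, 1] - n[:, 1] * h[:, 0]
    dot = np.einsum("ij,ij->i", n, h)
    theta_w = np.arctan2(cross, dot)
    return lam, theta_w, lam / speeds


def wall_impact(state: FishState, tank: TankGeometry) -> WallStimulus:
    """Wall stimulus (D_W, θ_W, D_W/v) for one fish strictly inside the tank."""
    d, a, t = wall_impact_arrays(
        state.position[None, :], np.array([state.heading]), np.array([state.speed]), tank
    )
    return WallStimulus(float(d[0]), float(a[0]), float(t[0]))


# ---------------------------------------------------------------------------
# pair stimuli
# ---------------------------------------------------------------------------

def pair_stimuli_arrays(positions, headings):
    """Full pairwise stimulus matrices ``(d, ψ, φ)``, each of shape (N, N).

    Entry [i, j] describes fish j as seen by focal fish i.  The diagonal and
    coincident pairs have ψ = 0 (their attraction contribution vanishes with
    d = 0 anyway).
    """
    pos = np.asarray(positions, dtype=float)
    headings = np.asarray(headings, dtype=float)
    delta = pos[None, :, :] - pos[:, None, :]  # [i, j] = x_j − x_i
    d = np.hypot(delta[..., 0], delta[..., 1])
    bearing_abs = np.arctan2(delta[..., 1], delta[..., 0])
    psi = wrap_angle(bearing_abs - headings[:, None])
    psi = np.where(d == 0.0, 0.0, psi)
    phi = wrap_angle(headings[None, :] - headings[:, None])
    return d, psi, phi


def pair_stimuli(focal: FishState, other: FishState) -> PairStimulus:
    """Stimulus (d, ψ, φ) of ``other`` as seen by ``focal``.

    Coincident positions yield ψ = 0 with a warning flag.
    """
    delta = other.position - focal.position
    d = float(np.hypot(*delta))
    coincident = d == 0.0
    if coincident:
        warnings.warn("coincident fish positions: bearing undefined, set to 0")
        psi = 0.0
    else:
        psi = wrap_angle(np.arctan2(delta[1], delta[0]) - focal.heading)
    phi = wrap_angle(other.heading - focal.heading)
    return PairStimulus(d, float(psi), float(phi), coincident)


# ---------------------------------------------------------------------------
# neighbor graphs
# ---------------------------------------------------------------------------

def _delaunay_adjacency(pos: np.ndarray) -> np.ndarray:
    n = len(pos)
    adj = np.zeros((n, n), dtype=bool)
    tri = Delaunay(pos)
    for simplex in tri.simplices:
        for a in simplex:
            for b in simplex:
                if a != b:
                    adj[a, b] = True
    return adj


def _chain_adjacency(pos: np.ndarray) -> np.ndarray:
    # collinear point sets: no triangulation exists; fall back to the 1D
    # chain (each point neighbors its sorted predecessor and successor)
    n = len(pos)
    centered = pos - pos.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    order = np.argsort(centered @ vt[0])
    adj = np.zeros((n, n), dtype=bool)
    for a, b in zip(order[:-1], order[1:]):
        adj[a, b] = adj[b, a] = True
    return adj


def _is_collinear(pos: np.ndarray, rtol: float = 1e-12) -> bool:
    centered = pos - pos.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return s[1] <= rtol * max(s[0], 1.0)


def adjacency_matrix(pos: np.ndarray, method: str, k: int | None = None) -> np.ndarray:
    """Boolean adjacency matrix of the interaction graph (fast core)."""
    n = len(pos)
    if method == "all":
        return ~np.eye(n, dtype=bool)

    if method == "voronoi_shell1":
        d2 = np.sum((pos[None] - pos[:, None]) ** 2, axis=-1)
        if np.any(d2[~np.eye(n, dtype=bool)] == 0.0):
            raise ValueError("duplicate points are not allowed under voronoi_shell1")
        if n <= 3 or _is_collinear(pos):
            if n <= 3 and not _is_collinear(pos):
                return ~np.eye(n, dtype=bool)  # 2 points, or one Delaunay triangle
            return _chain_adjacency(pos)
        try:
            return _delaunay_adjacency(pos)
        except QhullError:
            return _chain_adjacency(pos)

    if method == "knn":
        if k is None or k < 1:
            raise ValueError("knn method requires k >= 1")
        kk = min(k, n - 1)
        d2 = np.sum((pos[None] - pos[:, None]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        idx = np.argpartition(d2, kk - 1, axis=1)[:, :kk]
        adj = np.zeros((n, n), dtype=bool)
        adj[np.repeat(np.arange(n), kk), idx.ravel()] = True
        return adj

    raise ValueError(f"unknown neighborhood method {method!r}")


def neighbor_graph(positions, method: str = "voronoi_shell1", k: int | None = None) -> NeighborGraph:
    """Interaction graph over a point set.

    ``method``: ``"all"`` (complete graph), ``"voronoi_shell1"`` (first shell
    of Voronoi neighbors = Delaunay adjacency; symmetric), or ``"knn"`` with
    ``k`` nearest neighbors (directed; ``min(k, N−1)`` used).
    """
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    if n < 2:
        raise ValueError(f"need at least 2 positions, got {n}")
    tag = f"knn:{k}" if method == "knn" else method
    return NeighborGraph(adjacency_matrix(pos, method, k), tag)
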