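"""Stimulus/response function ω*: wall avoidance plus normalized social terms.

The target turning speed of focal fish i is

    ω*_i = f_W(D_W, θ_W) + (1/N_i) Σ_{j ∈ 𝒩_i} [ f_P(d_ij, ψ_ij) + f_V(φ_ij) ]

with

    f_W = k_w · cos(θ_W) · sign(θ_W) / T,   T = D_W / v  (time-to-impact mode)
    f_P = k_p · v^α_p · d · sin(ψ)          (attraction; linear in distance)
    f_V = k_v · v^α_v · sin(φ)              (alignment)

The social superposition is normalized by the neighbor count N_i, so wall
avoidance and the averaged neighbor influence keep the same relative weight
at every group size.  The wall term steers the fish away from a head-on
approach (it increases |θ_W|) and diverges as the time to impact vanishes,
which is what keeps trajectories inside the tank without any explicit
repulsion or reflection rule.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np

from .geometry import (
    FishState,
    NeighborGraph,
    PairStimulus,
    TankGeometry,
    WallStimulus,
    pair_stimuli,
    pair_stimuli_arrays,
    wall_impact,
    wall_impact_arrays,
)

__all__ = ["ModelParams", "TargetTurningSpeed", "wall_response", "pair_response",
           "target_turning_speed", "target_turning_speed_arrays"]


@dataclass
class ModelParams:
    """Behavioral constants of the schooling model.

    Parameters
    ----------
    wall_strength : float
        k_w, response scale of the wall-avoidance term (rad in
        time-to-impact mode).
    persistence_length : float
        l (m); the angular-velocity relaxation time is τ = l / v.
    noise_scale : float
        σ (rad·s^−3/2), scale of the Wiener increments driving ω.
    attract_coeff : float
        k_p, weight of the positional (attraction) term.
    align_coeff : float
        k_v, weight of the orientational (alignment) term.
    speed_exp_wall, speed_exp_attract, speed_exp_align : int
        Exponents α ∈ {0, 1} of the speed scaling v^α of each coefficient.
        α_w only applies in ``wall_mode="distance"``; in the default
        time-to-impact mode the wall speed dependence is carried by
        1/T = v / D_W already.
    wall_mode : str
        ``"time_to_impact"`` (default) or ``"distance"``.
    attract_saturation : float or None
        Optional saturation distance d_sat (m): the attraction distance
        factor becomes min(d, d_sat).  Off (None) by default; intended for
        open-space scenarios where the linear form cannot hold.
    """

    wall_strength: float = 5.0
    persistence_length: float = 0.2
    noise_scale: float = 0.8
    attract_coeff: float = 1.0
    align_coeff: float = 2.5
    speed_exp_wall: int = 1
    speed_exp_attract: int = 1
    speed_exp_align: int = 1
    wall_mode: str = "time_to_impact"
    attract_saturation: float | None = None

    def __post_init__(self):
        if not self.persistence_length > 0:
            raise ValueError("persistence_length must be > 0")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        for name in ("speed_exp_wall", "speed_exp_attract", "speed_exp_align"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1")
        if self.wall_mode not in ("time_to_impact", "distance"):
            raise ValueError(f"unknown wall_mode {self.wall_mode!r}")
        for name in ("wall_strength", "attract_coeff", "align_coeff"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def tau(self, speed):
        """Angular-velocity relaxation time τ = l / v (s)."""
        return self.persistence_length / np.asarray(speed, dtype=float)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)

    def scaled(self, factor: float) -> "ModelParams":
        """Copy with the two interaction strengths multiplied by ``factor``."""
        return replace(self, attract_coeff=self.attract_coeff * factor,
                       align_coeff=self.align_coeff * factor)


@dataclass
class TargetTurningSpeed:
    """ω* and its three components (rad/s); total = wall + attraction + alignment."""

    wall: float
    attraction: float
    alignment: float

    @property
    def total(self) -> float:
        return self.wall + self.attraction + self.alignment


def _wall_response_arrays(dist, theta_w, speeds, params: ModelParams, rng) -> np.ndarray:
    sign = np.sign(theta_w)
    zero = np.flatnonzero(sign == 0.0)
    if zero.size and rng is not None:
        # measure-zero head-on tie-break; draws consumed in fish-index order
        for i in zero:
            sign[i] = rng.choice((-1.0, 1.0))
    g = np.cos(theta_w) * sign
    if params.wall_mode == "time_to_impact":
        return params.wall_strength * g * speeds / dist
    return params.wall_strength * speeds**params.speed_exp_wall * g / dist


def wall_response(wall: WallStimulus, speed: float, params: ModelParams, rng=None) -> float:
    """Wall-avoidance component of ω* (rad/s) for one fish.

    Raises if the fish sits exactly on the wall (zero time to impact); a
    head-on θ_W = 0 gets a random turning sign from ``rng``.
    """
    if wall.time_to_impact <= 0 or wall.dist_to_impact <= 0:
        raise ValueError("fish on the wall: time to impact is zero")
    if wall.angle_to_normal == 0.0 and rng is None:
        raise ValueError("head-on wall approach requires an rng for the sign tie-break")
    out = _wall_response_arrays(
        np.array([wall.dist_to_impact]),
        np.array([wall.angle_to_normal]),
        np.array([wall.dist_to_impact / wall.time_to_impact]),
        params,
        rng,
    )
    return float(out[0])


def pair_response(pair: PairStimulus, speed: float, params: ModelParams) -> tuple[float, float]:
    """(attraction, alignment) components (rad/s) contributed by one neighbor."""
    d = pair.distance
    if params.attract_saturation is not None:
        d = min(d, params.attract_saturation)
    attraction = params.attract_coeff * speed**params.speed_exp_attract * d * np.sin(pair.bearing)
    alignment = params.align_coeff * speed**params.speed_exp_align * np.sin(pair.heading_diff)
    return float(attraction), float(alignment)


def target_turning_speed_arrays(positions, headings, speeds, adjacency,
                                tank: TankGeometry, params: ModelParams, rng=None):
    """Vectorized ω* components for all fish.

    Returns an (N, 3) array with columns (wall, attraction, alignment).
    The social term is the neighbor average; isolated fish get 0; the wall
    term is 0 in open space.
    """
    pos = np.asarray(positions, dtype=float)
    headings = np.asarray(headings, dtype=float)
    speeds = np.broadcast_to(np.asarray(speeds, dtype=float), (len(pos),))
    n = len(pos)
    out = np.zeros((n, 3))

    if tank.bounded:
        dist, theta_w, _ = wall_impact_arrays(pos, headings, speeds, tank)
        out[:, 0] = _wall_response_arrays(dist, theta_w, speeds, params, rng)

    if n > 1 and adjacency is not None and adjacency.any():
        d, psi, phi = pair_stimuli_arrays(pos, headings)
        if params.attract_saturation is not None:
            d = np.minimum(d, params.attract_saturation)
        att = d * np.sin(psi)
        ali = np.sin(phi)
        counts = adjacency.sum(axis=1)
        safe = np.maximum(counts, 1)
        vp = speeds**params.speed_exp_attract
        vv = speeds**params.speed_exp_align
        out[:, 1] = params.attract_coeff * vp * (att * adjacency).sum(axis=1) / safe
        out[:, 2] = params.align_coeff * vv * (ali * adjacency).sum(axis=1) / safe
    return out


def target_turning_speed(focal: int, states: list[FishState], graph: NeighborGraph | None,
                         tank: TankGeometry, params: ModelParams, rng=None) -> TargetTurningSpeed:
    """ω* of the fish with index ``focal`` given all current states.

    ``graph`` may be None for an isolated fish (social term is then 0).
    """
    n = len(states)
    if graph is not None and graph.n != n:
        raise ValueError(f"graph has {graph.n} nodes but {n} states were given")
    if not 0 <= focal < n:
        raise ValueError(f"focal index {focal} out of range for {n} states")
    st = states[focal]

    wall = 0.0
    if tank.bounded:
        wall = wall_response(wall_impact(st, tank), st.speed, params, rng)

    attraction = alignment = 0.0
    if graph is not None:
        nbrs = graph.neighbors(focal)
        if nbrs.size:
            for j in nbrs:
                a, al = pair_response(pair_stimuli(st, states[j]), st.speed, params)
                attraction += a
                alignment += al
            attraction /= nbrs.size
            alignment /= nbrs.size
    return TargetTurningSpeed(float(wall), float(attraction), float(alignment))
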