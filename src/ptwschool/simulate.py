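"""Time-stepping of the coupled angular-velocity SDEs.

Each fish's angular velocity relaxes toward its stimulus/response target
ω* with timescale τ = l/v and is driven by Wiener increments of scale σ:

    ω ← ω + (dt/τ)(ω* − ω) + σ √dt ξ,     ξ ~ N(0, 1)
    θ ← wrap(θ + ω dt)
    x ← x + v (cos θ, sin θ) dt

The neighbor graph is recomputed every step.  A position that lands outside
a bounded tank is radially projected back to (1 − 1e−6) R with heading
unchanged; such events are counted and surfaced (the model itself, via the
diverging wall term, is expected to keep fish inside — projections are a
numerical safety net, never silent).

Sampled output is a long-format table (t, id, x, y, heading, omega) on a
uniform frame grid (default 12 fps).  ``SimConfig.duration`` is the measured
window: the simulation integrates ``transient + duration`` seconds and
discards the transient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import TankGeometry, adjacency_matrix
from .interactions import ModelParams, target_turning_speed_arrays

try:  # optional acceleration of the inner step loop
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional dependency
    _HAVE_NUMBA = False

__all__ = ["SpeedSchedule", "SimConfig", "step", "simulate", "speed_schedule_scenario"]


@dataclass
class SpeedSchedule:
    """Piecewise-linear common speed profile v(t).

    ``times`` and ``values`` are breakpoints; outside the range the profile
    is held constant at the nearest endpoint value.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("breakpoint times must be strictly increasing")
        if np.any(self.values <= 0):
            raise ValueError("speeds must be strictly positive")

    def __call__(self, t: float) -> float:
        return float(np.interp(t, self.times, self.values))

    @classmethod
    def ramp(cls, v0: float, v1: float, t_start: float, t_ramp: float) -> "SpeedSchedule":
        """Hold v0, then ramp linearly to v1 over ``t_ramp`` seconds."""
        return cls(np.array([t_start, t_start + t_ramp]), np.array([v0, v1]))


@dataclass
class SimConfig:
    """Configuration of one simulation run.

    ``duration`` is the measured window after the transient; the run
    integrates ``transient + duration`` seconds in total.  ``speeds`` is a
    single common speed, a per-fish array, or a :class:`SpeedSchedule`.
    """

    tank: TankGeometry = field(default_factory=TankGeometry)
    n_fish: int = 2
    params: ModelParams = field(default_factory=ModelParams)
    speeds: float | np.ndarray | SpeedSchedule = 0.5
    dt: float = 1.0 / 48
    duration: float = 120.0
    transient: float = 20.0
    seed: int | None = None
    graph_method: str = "voronoi_shell1"
    knn_k: int | None = None
    fps_out: float = 12.0
    initial: tuple | None = None  # (positions (N,2), headings (N,), omegas (N,))
    init_radius_frac: float = 0.8

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration <= 0 or self.transient < 0:
            raise ValueError("need duration > 0 and transient >= 0")
        sub = 1.0 / (self.fps_out * self.dt)
        if sub < 1 - 1e-9:
            raise ValueError("dt must not exceed the output frame interval")
        if abs(sub - round(sub)) > 1e-6:
            raise ValueError(
                f"dt={self.dt} must divide the output frame interval 1/{self.fps_out}"
            )

    @property
    def substeps(self) -> int:
        """Integration steps per output frame."""
        return int(round(1.0 / (self.fps_out * self.dt)))

    def speed_at(self, t: float) -> np.ndarray:
        if isinstance(self.speeds, SpeedSchedule):
            return np.full(self.n_fish, self.speeds(t))
        return np.broadcast_to(np.asarray(self.speeds, dtype=float), (self.n_fish,)).copy()


def step(positions, headings, omegas, speeds, params: ModelParams, tank: TankGeometry,
         dt: float, rng, graph_method: str = "voronoi_shell1", knn_k: int | None = None,
         adjacency=None):
    """One Euler step of the coupled SDEs for all fish (arrays in, arrays out).

    Returns ``(positions, headings, omegas, n_projected)``.  ``adjacency``
    may be passed to reuse a precomputed graph (e.g. all-to-all); otherwise
    the neighbor graph is recomputed from the current positions.
    """
    n = len(positions)
    if adjacency is None and n > 1:
        adjacency = adjacency_matrix(positions, graph_method, knn_k)

    target = target_turning_speed_arrays(positions, headings, speeds, adjacency,
                                         tank, params, rng)
    omega_star = target.sum(axis=1)
    tau = params.persistence_length / speeds
    noise = params.noise_scale * np.sqrt(dt) * rng.standard_normal(n)
    omegas = omegas + (dt / tau) * (omega_star - omegas) + noise
    headings = headings + omegas * dt
    positions = positions + (speeds * dt)[:, None] * np.stack(
        [np.cos(headings), np.sin(headings)], axis=1)

    n_projected = 0
    if tank.bounded:
        rel = positions - tank.center
        r = np.hypot(rel[:, 0], rel[:, 1])
        outside = r >= tank.radius
        if np.any(outside):
            n_projected = int(outside.sum())
            scale = (1.0 - 1e-6) * tank.radius / r[outside]
            positions[outside] = tank.center + rel[outside] * scale[:, None]

    if not (np.all(np.isfinite(positions)) and np.all(np.isfinite(omegas))):
        raise FloatingPointError("non-finite state encountered during integration")
    return positions, headings, omegas, n_projected


def _build_kernel():
    """Compiled one-step update (two passes: targets from frozen states, then
    the state update).  Semantics match :func:`step` except that an exactly
    head-on wall approach (θ_W = 0, measure zero under the dynamics) turns
    with sign +1 instead of drawing a random sign."""

    @_njit(cache=False)
    def kernel(px, py, th, om, v, adj, knn_k, bounded, R, cx, cy,
               k_w, wall_time_mode, a_w, l, k_p, a_p, k_v, a_v, sat,
               dt, noise):
        n = px.shape[0]
        oms = np.empty(n)
        if knn_k > 0:
            adj[:, :] = False
        for i in range(n):
            ws = 0.0
            if bounded:
                hx = np.cos(th[i])
                hy = np.sin(th[i])
                rx = px[i] - cx
                ry = py[i] - cy
                b = rx * hx + ry * hy
                lam = -b + np.sqrt(b * b + R * R - (rx * rx + ry * ry))
                qx = (rx + lam * hx) / R
                qy = (ry + lam * hy) / R
                thw = np.arctan2(qx * hy - qy * hx, qx * hx + qy * hy)
                s = 1.0 if thw >= 0.0 else -1.0
                g = np.cos(thw) * s
                if wall_time_mode:
                    ws = k_w * g * v[i] / lam
                else:
                    ws = k_w * v[i] ** a_w * g / lam

            att = 0.0
            ali = 0.0
            cnt = 0
            if knn_k > 0:
                # k nearest neighbors selected in-loop (directed graph)
                kk = min(knn_k, n - 1)
                for _rep in range(kk):
                    best = -1
                    bestd = np.inf
                    for j in range(n):
                        if j == i or adj[i, j]:
                            continue
                        dx = px[j] - px[i]
                        dy = py[j] - py[i]
                        d2 = dx * dx + dy * dy
                        if d2 < bestd:
                            bestd = d2
                            best = j
                    if best >= 0:
                        adj[i, best] = True
            for j in range(n):
                if adj[i, j]:
                    cnt += 1
                    dx = px[j] - px[i]
                    dy = py[j] - py[i]
                    d = np.hypot(dx, dy)
                    if sat >= 0.0 and d > sat:
                        deff = sat
                    else:
                        deff = d
                    att += deff * np.sin(np.arctan2(dy, dx) - th[i])
                    ali += np.sin(th[j] - th[i])
            if cnt > 0:
                att = k_p * v[i] ** a_p * att / cnt
                ali = k_v * v[i] ** a_v * ali / cnt
            oms[i] = ws + att + ali

        proj = 0
        for i in range(n):
            tau = l / v[i]
            om[i] = om[i] + (dt / tau) * (oms[i] - om[i]) + noise[i]
            th[i] = th[i] + om[i] * dt
            px[i] += v[i] * dt * np.cos(th[i])
            py[i] += v[i] * dt * np.sin(th[i])
            if bounded:
                rx = px[i] - cx
                ry = py[i] - cy
                r = np.hypot(rx, ry)
                if r >= R:
                    sc = (1.0 - 1e-6) * R / r
                    px[i] = cx + rx * sc
                    py[i] = cy + ry * sc
                    proj += 1
        return proj

    return kernel


_KERNEL = None


def _get_kernel():
    global _KERNEL
    if _KERNEL is None and _HAVE_NUMBA:
        _KERNEL = _build_kernel()
    return _KERNEL


def _initial_states(config: SimConfig, rng):
    if config.initial is not None:
        pos, heading, omega = config.initial
        pos = np.array(pos, dtype=float).reshape(config.n_fish, 2)
        heading = np.array(heading, dtype=float).reshape(config.n_fish)
        omega = np.array(omega, dtype=float).reshape(config.n_fish)
        return pos, heading, omega
    n = config.n_fish
    r = config.init_radius_frac * config.tank.radius * np.sqrt(rng.random(n))
    ang = rng.uniform(-np.pi, np.pi, n)
    pos = config.tank.center + np.stack([r * np.cos(ang), r * np.sin(ang)], axis=1)
    heading = rng.uniform(-np.pi, np.pi, n)
    return pos, heading, np.zeros(n)


def simulate(config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Run one simulation and return the sampled track table.

    The output frame grid starts at t = 0 after the transient (the state at
    the start of the measured window itself is included only when
    ``transient == 0``).  Bit-reproducible for a fixed seed.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    pos, heading, omega = _initial_states(config, rng)
    if config.tank.bounded:
        rel = pos - config.tank.center
        if np.any(np.hypot(rel[:, 0], rel[:, 1]) >= config.tank.radius):
            raise ValueError("initial position outside the bounded tank")

    n = config.n_fish
    dt = config.dt
    sub = config.substeps
    n_steps = int(round((config.transient + config.duration) / dt))
    k_trans = int(round(config.transient / dt))

    # fixed adjacency when the graph cannot change between steps
    fixed_adj = None
    if n == 1:
        fixed_adj = np.zeros((1, 1), dtype=bool)
    elif config.graph_method == "all" or n == 2:
        fixed_adj = ~np.eye(n, dtype=bool)

    frames = []
    ids = np.arange(n)

    # the measured-window frame grid starts at t = 0: the first retained
    # frame is the one right after the transient (or the initial state when
    # transient == 0)
    t_offset = (k_trans + sub) * dt if k_trans else 0.0

    def record(k):
        t_out = k * dt - t_offset
        frames.append((t_out, pos.copy(), heading.copy(), omega.copy()))
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(omega))):
            raise FloatingPointError(
                f"non-finite state at t={k * dt:.3f} s (seed={seed})")

    if k_trans == 0:
        record(0)
    n_projected = 0
    kernel = _get_kernel()
    p = config.params
    scheduled = isinstance(config.speeds, SpeedSchedule)
    speeds = config.speed_at(0.0)

    if kernel is not None:
        px, py = pos[:, 0].copy(), pos[:, 1].copy()
        knn_k = 0
        scratch_adj = fixed_adj
        if fixed_adj is None:
            if config.graph_method == "knn" and n > 3:
                knn_k = int(config.knn_k)
                scratch_adj = np.zeros((n, n), dtype=bool)
        args = (np.float64(config.tank.radius), np.float64(config.tank.center[0]),
                np.float64(config.tank.center[1]), np.float64(p.wall_strength),
                p.wall_mode == "time_to_impact", np.float64(p.speed_exp_wall),
                np.float64(p.persistence_length), np.float64(p.attract_coeff),
                np.float64(p.speed_exp_attract), np.float64(p.align_coeff),
                np.float64(p.speed_exp_align),
                np.float64(-1.0 if p.attract_saturation is None else p.attract_saturation),
                np.float64(dt))
        for k in range(1, n_steps + 1):
            if scheduled:
                speeds = config.speed_at((k - 1) * dt)
            if scratch_adj is None:  # voronoi (or small-N) graph, every step
                adj = adjacency_matrix(np.stack([px, py], axis=1),
                                       config.graph_method, config.knn_k)
            else:
                adj = scratch_adj
            noise = p.noise_scale * np.sqrt(dt) * rng.standard_normal(n)
            n_projected += kernel(px, py, heading, omega, speeds, adj, knn_k,
                                  config.tank.bounded, *args, noise)
            if k % sub == 0 and k > k_trans:
                pos = np.stack([px, py], axis=1)
                record(k)
    else:  # pragma: no cover - exercised only without numba
        for k in range(1, n_steps + 1):
            if scheduled:
                speeds = config.speed_at((k - 1) * dt)
            pos, heading, omega, np_k = step(
                pos, heading, omega, speeds, config.params, config.tank, dt, rng,
                config.graph_method, config.knn_k, adjacency=fixed_adj)
            n_projected += np_k
            if k % sub == 0 and k > k_trans:
                record(k)

    if n_projected > 1e-3 * n_steps * n:
        warnings.warn(
            f"{n_projected} boundary projections (> 0.1% of steps): wall term "
            "too weak or dt too coarse for containment")

    t = np.repeat([f[0] for f in frames], n)
    table = pd.DataFrame({
        "t": t,
        "id": np.tile(ids, len(frames)),
        "x": np.concatenate([f[1][:, 0] for f in frames]),
        "y": np.concatenate([f[1][:, 1] for f in frames]),
        "heading": np.concatenate([(np.mod(f[2] + np.pi, 2 * np.pi) - np.pi) for f in frames]),
        "omega": np.concatenate([f[3] for f in frames]),
    })
    table.attrs.update({
        "fps": config.fps_out,
        "dt": dt,
        "seed": seed,
        "n_projections": n_projected,
        "n_steps": n_steps,
        "tank_radius": config.tank.radius,
        "bounded": config.tank.bounded,
        "params": config.params.to_dict(),
    })
    return table


def speed_schedule_scenario(config: SimConfig, schedule: SpeedSchedule,
                            seed: int | None = None) -> pd.DataFrame:
    """Simulate a group in open space under a time-varying common speed.

    Used for the shoaling↔schooling transition scenarios: a slow speed ramp
    raises the group polarization; an abrupt speed step produces a transient
    flash-expansion of nearest-neighbor distances.
    """
    open_tank = TankGeometry(radius=config.tank.radius, center=config.tank.center,
                             bounded=False)
    cfg = replace(config, tank=open_tank, speeds=schedule)
    return simulate(cfg, seed=seed)
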