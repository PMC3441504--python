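"""Experiment-like synthetic replicate sets and track-table file I/O.

The generator emulates the design of the tank experiments the model targets:
groups of N ∈ {1, 2, 5, 10, 15, 30} fish in a circular tank of 2 m radius,
five replicates per size, 120 s of measurement sampled at 12 frames/s, and a
per-replicate common swimming speed (fish in a replicate synchronize their
speed; the value differs between replicates).  An optional size-dependent
scaling of the two interaction strengths emulates the reduced reactivity to
neighbors observed in the largest (densest) groups.  The manifest records
every true parameter and seed, so any replicate can be regenerated
bit-exactly — the ground truth for parameter-recovery studies.

Tracks are exchanged as long-format CSV with header ``t,id,x,y`` (extra
columns preserved), the minimal superset of what 2D tracking software
exports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import TankGeometry
from .interactions import ModelParams
from .simulate import SimConfig, simulate

__all__ = ["ExperimentDesign", "make_dataset", "regenerate_replicate",
           "read_tracks", "write_tracks", "save_manifest", "load_manifest"]

log = logging.getLogger(__name__)


@dataclass
class ExperimentDesign:
    """Design of a synthetic replicate set (sizes, replicates, sampling).

    ``speed_range`` is the uniform range the per-replicate common speed is
    drawn from.  ``interaction_scaling_gamma``, when set, multiplies the two
    interaction coefficients by (2/N)^γ for N ≥ 2, imposing a known decrease
    of interaction strength with group size.  ``body_length`` (m) is only a
    reporting unit.
    """

    group_sizes: tuple = (1, 2, 5, 10, 15, 30)
    replicates: int = 5
    duration: float = 120.0
    transient: float = 20.0
    fps: float = 12.0
    dt: float = 1.0 / 48
    tank_radius: float = 2.0
    speed_range: tuple = (0.1, 1.0)
    body_length: float = 0.1
    noise_sd: float = 0.0
    seed: int = 0
    interaction_scaling_gamma: float | None = None
    graph_method: str = "voronoi_shell1"

    def __post_init__(self):
        if self.replicates < 1 or any(n < 1 for n in self.group_sizes):
            raise ValueError("counts must be positive")
        if not self.speed_range[0] > 0:
            raise ValueError("speeds must be positive")

    def scale_factor(self, n: int) -> float:
        if self.interaction_scaling_gamma is None or n < 2:
            return 1.0
        return (2.0 / n) ** self.interaction_scaling_gamma


def _replicate_seeds(design: ExperimentDesign):
    """Deterministic per-replicate seed material derived from the master seed."""
    combos = [(n, r) for n in design.group_sizes for r in range(design.replicates)]
    out = {}
    for i, (n, r) in enumerate(combos):
        ss = np.random.SeedSequence(entropy=design.seed, spawn_key=(i,))
        sim_seed, speed_seed, noise_seed = ss.generate_state(3, dtype=np.uint32)
        out[(n, r)] = (int(sim_seed), int(speed_seed), int(noise_seed))
    return out


def _simulate_replicate(design: ExperimentDesign, params: ModelParams,
                        size: int, seeds: tuple) -> tuple[pd.DataFrame, dict]:
    sim_seed, speed_seed, noise_seed = seeds
    speed = float(np.random.default_rng(speed_seed).uniform(*design.speed_range))
    factor = design.scale_factor(size)
    rep_params = params.scaled(factor)
    cfg = SimConfig(
        tank=TankGeometry(radius=design.tank_radius),
        n_fish=size, params=rep_params, speeds=speed, dt=design.dt,
        duration=design.duration, transient=design.transient,
        graph_method=design.graph_method, fps_out=design.fps, seed=sim_seed)
    track = simulate(cfg)
    n_proj = int(track.attrs.get("n_projections", 0))
    if design.noise_sd > 0:
        noise_rng = np.random.default_rng(noise_seed)
        track = track[["t", "id", "x", "y"]].copy()
        track[["x", "y"]] += noise_rng.normal(0.0, design.noise_sd,
                                              (len(track), 2))
    else:
        track = track[["t", "id", "x", "y"]].copy()
    track.attrs["fps"] = design.fps
    info = {"size": size, "speed": speed, "scale_factor": factor,
            "true_params": rep_params.to_dict(),
            "seeds": {"sim": seeds[0], "speed": seeds[1], "noise": seeds[2]},
            "n_projections": n_proj}
    return track, info


def make_dataset(design: ExperimentDesign, params: ModelParams | None = None
                 ) -> tuple[dict, dict]:
    """Simulate the full replicate set.

    Returns ``(tracks, manifest)`` where ``tracks`` maps (size, replicate) to
    a (t, id, x, y) table and the manifest records the design, the base
    parameters and the per-replicate ground truth (speed, scale factor, true
    parameters, seeds).
    """
    if params is None:
        params = ModelParams()
    seeds = _replicate_seeds(design)
    tracks, reps = {}, {}
    for (n, r), s in seeds.items():
        track, info = _simulate_replicate(design, params, n, s)
        tracks[(n, r)] = track
        reps[f"N{n}_rep{r}"] = info
    manifest = {"design": asdict(design), "base_params": params.to_dict(),
                "replicates": reps}
    return tracks, manifest


def regenerate_replicate(manifest: dict, size: int, rep: int) -> pd.DataFrame:
    """Bit-exact regeneration of one replicate from its manifest entry."""
    design = ExperimentDesign(**{**manifest["design"],
                                 "group_sizes": tuple(manifest["design"]["group_sizes"]),
                                 "speed_range": tuple(manifest["design"]["speed_range"])})
    params = ModelParams.from_dict(manifest["base_params"])
    info = manifest["replicates"][f"N{size}_rep{rep}"]
    seeds = (info["seeds"]["sim"], info["seeds"]["speed"], info["seeds"]["noise"])
    track, _ = _simulate_replicate(design, params, size, seeds)
    return track


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_REQUIRED = ("t", "id", "x", "y")


def write_tracks(track: pd.DataFrame, path) -> None:
    """Write a track table as CSV at full float precision (lossless)."""
    cols = [c for c in _REQUIRED if c in track.columns]
    cols += [c for c in track.columns if c not in cols]
    track[cols].to_csv(path, index=False)


def read_tracks(path, fps: float | None = None) -> pd.DataFrame:
    """Read a track CSV, canonically sorted by (t, id), grid-validated.

    Frame times must lie on a uniform grid (missing frames for a fish are
    allowed and logged as gaps; off-grid times are an error listing the
    offending values).  Unknown columns are preserved with a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as e:  # surface malformed rows with context
        raise ValueError(f"malformed track file {path}: {e}") from e
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in _REQUIRED + ("heading", "omega")]
    if extra:
        log.warning("%s: unknown columns preserved: %s", path, extra)
    bad = df[_list_nonnumeric(df)].index.tolist() if _list_nonnumeric(df).any() else []
    if bad:
        raise ValueError(f"{path}: non-numeric values at rows {bad[:5]}")
    df = df.sort_values(["t", "id"], kind="stable").reset_index(drop=True)

    ts = np.sort(df["t"].unique())
    if len(ts) > 1:
        step = 1.0 / fps if fps else float(np.median(np.diff(ts)))
        k = (ts - ts[0]) / step
        off = np.abs(k - np.round(k)) > 1e-6
        if off.any():
            raise ValueError(
                f"{path}: frame times off the uniform grid: {ts[off][:5].tolist()}")
        for fid, sub in df.groupby("id"):
            kf = np.round((np.sort(sub["t"].unique()) - ts[0]) / step).astype(int)
            gaps = int(kf[-1] - kf[0] + 1 - len(kf))
            if gaps:
                log.warning("%s: fish %s has %d missing frame(s)", path, fid, gaps)
        df.attrs["fps"] = 1.0 / step
    if fps:
        df.attrs["fps"] = fps
    return df


def _list_nonnumeric(df: pd.DataFrame):
    mask = pd.Series(False, index=df.index)
    for c in _REQUIRED:
        mask |= pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()
    return mask


def save_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2))


def load_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
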