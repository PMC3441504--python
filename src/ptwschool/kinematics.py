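"""Reconstruction of headings, speeds and angular velocities from sampled tracks.

Headings are taken as the directions of successive displacement vectors
(chords), unwrapped so that no per-frame increment exceeds π.  The angular
velocity at frame n is the difference of the two chords adjacent to n,

    ω_n = (θ̃_n − θ̃_{n−1}) · fps,

which is centered at frame n because each chord direction sits at a
half-frame.  A separate heading estimate for stimulus evaluation at frame n
uses the central displacement x_{n+1} − x_{n−1}.  Zero-displacement frames
are flagged and excluded; missing frames split a fish's series into
segments.  For circular motion the chord construction is exact (the turn
angle between successive chords is exactly ωΔt).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = ["FishKinematics", "Kinematics", "kinematics_from_track"]


@dataclass
class FishKinematics:
    """Per-fish kinematic series on the global frame grid (NaN = invalid)."""

    fish_id: int
    t: np.ndarray          # global frame times (F,)
    position: np.ndarray   # (F, 2)
    chord: np.ndarray      # (F,) unwrapped chord heading of x[n] → x[n+1]
    theta_hat: np.ndarray  # (F,) heading estimate at frame n (central displacement)
    omega: np.ndarray      # (F,) angular velocity, rad/s
    speed: np.ndarray      # (F,) chord speed, m/s
    v_bar: float           # track-mean speed
    n_excluded: int        # zero-displacement frames flagged and excluded

    @property
    def valid(self) -> np.ndarray:
        """Frames with both a heading estimate and an angular velocity."""
        return np.isfinite(self.omega) & np.isfinite(self.theta_hat)


@dataclass
class Kinematics:
    """Kinematic series of all fish in a track, plus the frame grid."""

    fish: dict
    dt: float
    fps: float
    t: np.ndarray
    source: str = "positions"  # "positions" (chord differences) or "columns"

    def __getitem__(self, fish_id: int) -> FishKinematics:
        return self.fish[fish_id]


def _frame_grid(track: pd.DataFrame, fps: float | None):
    ts = np.sort(track["t"].unique())
    if len(ts) < 2:
        raise ValueError("need at least 2 frames")
    if fps is None:
        dt = float(np.median(np.diff(ts)))
    else:
        dt = 1.0 / fps
    idx = (ts - ts[0]) / dt
    if np.max(np.abs(idx - np.round(idx))) > 1e-6:
        off = ts[np.abs(idx - np.round(idx)) > 1e-6][:5]
        raise ValueError(f"track times do not lie on a uniform grid (e.g. t={off})")
    n_frames = int(round(idx[-1])) + 1
    grid = ts[0] + dt * np.arange(n_frames)
    return grid, dt


def _runs(mask: np.ndarray):
    """Maximal runs of consecutive True entries, as (start, stop) slices."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    return list(zip(starts, stops))


def kinematics_from_track(track: pd.DataFrame, fps: float | None = None,
                          use_state_columns: bool = False,
                          smooth: tuple | None = None) -> Kinematics:
    """Reconstruct per-fish heading/ω/speed series from a (t, id, x, y) table.

    With ``use_state_columns=True`` and heading/omega columns present (e.g.
    simulator output), those are used directly instead of finite differences
    of positions; this is the exact-state path for validating the estimation
    machinery in its own model class.

    ``smooth=(window, order)`` applies Savitzky–Golay smoothing to the
    position series of each contiguous segment before differencing —
    intended for tracks with appreciable observation noise (clean simulated
    positions should be left unsmoothed: any smoothing slightly biases the
    recovered relaxation dynamics).
    """
    fps_attr = track.attrs.get("fps") if fps is None else fps
    grid, dt = _frame_grid(track, fps_attr)
    fpsv = 1.0 / dt
    n_frames = len(grid)
    have_state = use_state_columns and {"heading", "omega"} <= set(track.columns)
    if use_state_columns and not have_state:
        raise ValueError("use_state_columns=True but heading/omega columns missing")

    fish = {}
    for fid, sub in track.groupby("id", sort=True):
        sub = sub.sort_values("t")
        fi = np.round((sub["t"].to_numpy() - grid[0]) / dt).astype(int)
        pos = np.full((n_frames, 2), np.nan)
        pos[fi, 0] = sub["x"].to_numpy()
        pos[fi, 1] = sub["y"].to_numpy()

        chord = np.full(n_frames, np.nan)
        theta_hat = np.full(n_frames, np.nan)
        omega = np.full(n_frames, np.nan)
        speed = np.full(n_frames, np.nan)
        n_excluded = 0

        present = np.isfinite(pos[:, 0])
        for a, b in _runs(present):
            if b - a < 2:
                continue
            if smooth is not None and b - a > smooth[0]:
                window, order = smooth
                pos[a:b] = savgol_filter(pos[a:b], window, order, axis=0)
            disp = np.diff(pos[a:b], axis=0)
            norm = np.hypot(disp[:, 0], disp[:, 1])
            ok = norm > 0.0
            n_excluded += int((~ok).sum())
            # zero-displacement chords break the run into sub-runs
            for c, d in _runs(ok):
                m = d - c  # chords in this sub-run
                th = np.unwrap(np.arctan2(disp[c:d, 1], disp[c:d, 0]))
                chord[a + c:a + d] = th
                speed[a + c:a + d] = norm[c:d] * fpsv
                if m >= 2:
                    omega[a + c + 1:a + d] = np.diff(th) * fpsv
                    cen = pos[a + c + 2:a + d + 1] - pos[a + c:a + d - 1]
                    theta_hat[a + c + 1:a + d] = np.arctan2(cen[:, 1], cen[:, 0])

        if have_state:
            theta_hat[:] = np.nan
            omega[:] = np.nan
            hh = sub["heading"].to_numpy()
            oo = sub["omega"].to_numpy()
            theta_hat[fi] = hh
            omega[fi] = oo

        vbar = float(np.nanmean(speed)) if np.any(np.isfinite(speed)) else np.nan
        fish[int(fid)] = FishKinematics(int(fid), grid, pos, chord, theta_hat,
                                        omega, speed, vbar, n_excluded)
    return Kinematics(fish, dt, fpsv, grid,
                      source="columns" if have_state else "positions")
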