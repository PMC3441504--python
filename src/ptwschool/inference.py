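"""Parametric inversion of the schooling model from sampled trajectories.

The angular velocity of fish i relaxes toward the stimulus/response target
ω*_i with timescale τ_i = l / v̄_i.  Over one frame interval Δt this gives
the discrete-time regression

    Δω_n = g(Δt/τ) · (k_w S_w + k_p v̄^{α_p} S_p + k_v v̄^{α_v} S_v − ω_n) + ε_n

with stimulus regressors computed from the observed configuration at frame n:

    S_w = cos(θ_W) sign(θ_W) · v̄ / D_W          (wall, time-to-impact form)
    S_p = (1/N_i) Σ_j d_ij sin ψ_ij              (normalized attraction)
    S_v = (1/N_i) Σ_j sin φ_ij                   (normalized alignment)

Estimating this regression naively is subtly inconsistent when ω is
reconstructed from positions: the chord-difference ω̃ is a triangle-kernel
average of the true process, and the stimuli are measured from the *same*
smoothed positions, so regressor and disturbance share noise
(errors-in-variables).  The default fit therefore uses instrumental
variables: the regressors lagged by two frames lie entirely outside the
smoothing windows of the response, and for non-overlapping windows the OU
covariances decay exactly like e^(−Δt/τ), so the IV moment conditions hold
with the exact-relaxation gain g = 1 − e^(−Δt/τ) and no kernel correction
(``method="iv"``, the default).

``method="nls"`` performs plain nonlinear least squares with a choice of
relaxation gain (``discretization``):

* ``"euler"``    g = Δt/τ — the literal Ito/Euler discretization; exact on
  full-rate simulator state output.
* ``"exact"``    g = 1 − exp(−Δt/τ) — the exact OU one-step relaxation, for
  point-sampled angular velocities at a coarse frame interval.
* ``"filtered"`` g = 1 − ρ₁(Δt/τ) — the population lag-1 gain of
  chord-difference angular velocities (see :mod:`ptwschool.oucorr`); it
  de-biases τ for an isolated fish, but cannot remove the shared-noise
  contamination of the social stimuli (the Euler gain applied to such data
  overestimates τ by tens of percent regardless of the frame rate).

σ is recovered from the residual variance with the conversion matching the
gain and the observation path (for ``"euler"`` it is the classical
σ̂² = Var(ε)/Δt; for position-reconstructed series the kernel-attenuated
variance of :mod:`ptwschool.oucorr` is inverted).

The public surface is statsmodels-like: build a :class:`SchoolingModel` from
tracks, call :meth:`~SchoolingModel.fit`, inspect the returned
:class:`SchoolingFitResult` (estimates, standard errors, σ̂, residual
diagnostics, binned stimulus–response curves, ``summary()``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from . import oucorr
from .geometry import TankGeometry, neighbor_graph, pair_stimuli_arrays, wall_impact_arrays
from .kinematics import Kinematics, kinematics_from_track

__all__ = ["SchoolingModel", "SchoolingFitResult", "build_regression", "fit_params",
           "residual_diagnostics", "stimulus_response_curves"]

_PARAM_NAMES = ("k_w", "l", "k_p", "k_v")
_BOUNDS_DEFAULT = {"k_w": (0.0, 100.0), "l": (0.01, 5.0),
                   "k_p": (0.0, 100.0), "k_v": (0.0, 100.0)}
_X0_DEFAULT = {"k_w": 1.0, "l": 0.2, "k_p": 1.0, "k_v": 1.0}


# ---------------------------------------------------------------------------
# regression records
# ---------------------------------------------------------------------------

def build_regression(kin: Kinematics, tank: TankGeometry,
                     graph_method: str = "voronoi_shell1", knn_k: int | None = None,
                     wall_mode: str = "time_to_impact",
                     attract_saturation: float | None = None,
                     series: int = 0) -> pd.DataFrame:
    """One record per usable frame transition of each fish.

    Columns: series, fish, t, omega, domega, s_wall, s_att, s_align, n_i,
    v_bar.  ``s_wall`` carries the speed factor of the time-to-impact form
    (v̄/D_W) so that k_w multiplies it directly; in ``wall_mode="distance"``
    it is 1/D_W and the fit applies k_w·v̄^α_w.
    """
    fids = sorted(kin.fish)
    F = len(kin.t)
    n = len(fids)
    valid = np.zeros((n, F), dtype=bool)
    pos = np.full((n, F, 2), np.nan)
    theta = np.full((n, F), np.nan)
    omega = np.full((n, F), np.nan)
    for a, fid in enumerate(fids):
        fk = kin.fish[fid]
        valid[a] = fk.valid
        pos[a] = fk.position
        theta[a] = fk.theta_hat
        omega[a] = fk.omega
    vbar = np.array([kin.fish[f].v_bar for f in fids])

    rows = []
    for f in range(F - 1):
        here = valid[:, f]
        if not here.any():
            continue
        idx = np.flatnonzero(here)
        p = pos[idx, f]
        th = theta[idx, f]
        m = len(idx)

        s_wall = np.zeros(m)
        if tank.bounded:
            inside = np.hypot(*(p - tank.center).T) < tank.radius
            if inside.all():
                dw, thw, _ = wall_impact_arrays(p, th, np.ones(m), tank)
                if wall_mode == "time_to_impact":
                    s_wall = np.cos(thw) * np.sign(thw) * vbar[idx] / dw
                else:
                    s_wall = np.cos(thw) * np.sign(thw) / dw
            # frames with a reconstructed position on/outside the wall are
            # unusable for the wall stimulus; drop them
            else:
                continue

        s_att = np.zeros(m)
        s_align = np.zeros(m)
        n_i = np.zeros(m, dtype=int)
        if m > 1:
            adj = neighbor_graph(p, graph_method, knn_k).adjacency
            d, psi, phi = pair_stimuli_arrays(p, th)
            if attract_saturation is not None:
                d = np.minimum(d, attract_saturation)
            n_i = adj.sum(axis=1)
            safe = np.maximum(n_i, 1)
            s_att = (d * np.sin(psi) * adj).sum(axis=1) / safe
            s_align = (np.sin(phi) * adj).sum(axis=1) / safe

        usable = valid[idx, f + 1]
        for k, a in enumerate(idx):
            if not usable[k]:
                continue
            rows.append((series, fids[a], kin.t[f], omega[a, f],
                         omega[a, f + 1] - omega[a, f],
                         s_wall[k], s_att[k], s_align[k], n_i[k], vbar[a]))

    rec = pd.DataFrame(rows, columns=["series", "fish", "t", "omega", "domega",
                                      "s_wall", "s_att", "s_align", "n_i", "v_bar"])
    rec.attrs["dt"] = kin.dt
    rec.attrs["wall_mode"] = wall_mode
    rec.attrs["source"] = kin.source
    return rec


# ---------------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------------

@dataclass
class SchoolingFitResult:
    """Estimates, uncertainties and diagnostics of one model fit."""

    params: dict
    bse: dict
    sigma_hat: float
    records: pd.DataFrame
    residuals: np.ndarray
    dt: float
    mode: str
    discretization: str
    active: tuple
    speed_exponents: dict
    success: bool
    message: str
    at_bounds: tuple = ()
    sigma_by_group: dict = field(default_factory=dict)
    nfev: int = 0

    @property
    def tau_by_group(self) -> dict:
        l = self.params["l"]
        return {g: l / v for g, v in
                self.records.groupby(["series", "fish"])["v_bar"].first().items()}

    def summary(self) -> str:
        lines = ["Schooling model fit",
                 "=" * 52,
                 f"mode: {self.mode}   discretization: {self.discretization}   "
                 f"records: {len(self.records)}",
                 f"converged: {self.success}   dt = {self.dt:.5f} s",
                 "-" * 52,
                 f"{'param':>6} {'estimate':>12} {'std err':>12}"]
        units = {"k_w": "rad", "l": "m", "k_p": "rad/m/s", "k_v": "rad/s"}
        for name in _PARAM_NAMES:
            v = self.params.get(name, np.nan)
            se = self.bse.get(name, np.nan)
            tag = " (at bound)" if name in self.at_bounds else ""
            lines.append(f"{name:>6} {v:>12.5g} {se:>12.3g}  [{units[name]}]{tag}")
        lines.append(f"{'sigma':>6} {self.sigma_hat:>12.5g} {'':>12}  [rad s^-3/2]")
        lines.append("=" * 52)
        return "\n".join(lines)

    # -- diagnostics --------------------------------------------------------

    def residual_diagnostics(self) -> dict:
        """QQ data against normal quantiles, normality correlation, lag-1
        residual autocorrelation."""
        r = self.residuals
        z = (r - r.mean()) / r.std()
        sample = np.sort(z)
        theo = sps.norm.ppf((np.arange(1, len(z) + 1) - 0.5) / len(z))
        qq_corr = float(np.corrcoef(sample, theo)[0, 1])
        acs = []
        for _, g in self.records.assign(resid=r).groupby(["series", "fish"]):
            v = g["resid"].to_numpy()
            if len(v) > 2:
                acs.append(np.corrcoef(v[:-1], v[1:])[0, 1])
        return {"qq_theoretical": theo, "qq_sample": sample, "qq_corr": qq_corr,
                "lag1_autocorr": float(np.mean(acs)) if acs else np.nan}

    def stimulus_response_curves(self, n_bins: int = 15, min_count: int = 10) -> dict:
        """Binned residual stimulus–response curves, one per stimulus.

        For each stimulus, the other two fitted components are subtracted
        from the implied target response (Δω/g + ω); the remainder is binned
        against the (speed-scaled) stimulus.  Under the model each curve is
        a line through the origin with slope equal to the fitted coefficient.
        """
        rec = self.records
        g = self._gain(self.params["l"])
        target = rec["domega"].to_numpy() / g + rec["omega"].to_numpy()
        cols = self._scaled_columns()
        out = {}
        for name, key in (("wall", "k_w"), ("attract", "k_p"), ("align", "k_v")):
            if key not in self.active:
                continue
            u = cols[key]
            others = sum(self.params[k2] * cols[k2]
                         for k2 in self.active if k2 not in (key, "l"))
            y = target - others
            edges = np.quantile(u, np.linspace(0, 1, n_bins + 1))
            edges = np.unique(edges)
            which = np.clip(np.digitize(u, edges[1:-1]), 0, len(edges) - 2)
            rows = []
            for b in range(len(edges) - 1):
                sel = which == b
                if sel.sum() < min_count:
                    continue
                rows.append((u[sel].mean(), y[sel].mean(), y[sel].std(ddof=1),
                             int(sel.sum())))
            out[name] = {
                "bins": pd.DataFrame(rows, columns=["stimulus", "mean", "sd", "count"]),
                "slope": self.params[key],
            }
        return out

    # -- internals shared with the fit --------------------------------------

    def _scaled_columns(self) -> dict:
        return _scaled_cols(self.records, self.speed_exponents)

    def _gain(self, l: float) -> np.ndarray:
        x = self.dt * self.records["v_bar"].to_numpy() / l
        return _gain(x, self.discretization)


def _scaled_cols(rec: pd.DataFrame, speed_exponents: dict) -> dict:
    v = rec["v_bar"].to_numpy()
    a_w = speed_exponents.get("wall", 1)
    a_p = speed_exponents.get("attract", 1)
    a_v = speed_exponents.get("align", 1)
    wall = rec["s_wall"].to_numpy()
    if rec.attrs.get("wall_mode", "time_to_impact") == "distance":
        wall = wall * v**a_w
    return {"k_w": wall,
            "k_p": rec["s_att"].to_numpy() * v**a_p,
            "k_v": rec["s_align"].to_numpy() * v**a_v}


def _gain(x, discretization: str):
    if discretization == "euler":
        return x
    if discretization in ("exact", "iv"):
        return 1.0 - np.exp(-x)
    if discretization == "filtered":
        return oucorr.gain_filtered(x)
    raise ValueError(f"unknown discretization {discretization!r}")


def _sigma2_from_resid(r2: float, tau: float, dt: float, discretization: str,
                       source: str) -> float:
    """Convert a per-fish residual variance into a σ² estimate.

    The conversion depends on the relaxation gain used and on whether ω was
    point-sampled (state columns) or reconstructed by chord differences
    (triangle-kernel averaged), whose attenuated covariances come from
    :mod:`ptwschool.oucorr`.
    """
    x = dt / tau
    if discretization == "euler":
        return r2 / dt
    if source == "columns":
        return 2.0 * r2 / (tau * (1.0 - np.exp(-2.0 * x)))
    c0 = oucorr.var_factor(x)
    rho = oucorr.rho1(x)
    if discretization in ("exact", "iv"):
        denom = c0 * (1.0 + np.exp(-2.0 * x)) - 2.0 * np.exp(-x) * rho * c0
    else:  # filtered lag-1 gain
        denom = c0 * (1.0 - rho**2)
    return 2.0 * r2 / (tau * denom)


def _lag_pairs_multi(rec: pd.DataFrame, dt: float, lags=(2,)):
    """Align each record with the records ``lags`` frames earlier of the same
    fish (instrument rows); records without all matches are dropped."""
    cur = []
    lagged = [[] for _ in lags]
    for _, g in rec.groupby(["series", "fish"], sort=False):
        g = g.sort_values("t")
        k = np.round(g["t"].to_numpy() / dt).astype(int)
        row = pd.Series(np.arange(len(g)), index=k)
        preds = [row.reindex(k - lag).to_numpy() for lag in lags]
        ok = np.all(np.isfinite(preds), axis=0)
        cur.append(g.iloc[np.flatnonzero(ok)])
        for out, pred in zip(lagged, preds):
            out.append(g.iloc[pred[ok].astype(int)])
    cur = pd.concat(cur, ignore_index=True)
    cur.attrs.update(rec.attrs)
    outs = []
    for chunks in lagged:
        lg = pd.concat(chunks, ignore_index=True)
        lg.attrs.update(rec.attrs)
        outs.append(lg)
    return cur, outs


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class SchoolingModel:
    """Discrete-time regression model of the turning response, built from
    trajectory data.

    Use :meth:`from_tracks` for the common case; the constructor accepts a
    prebuilt record table (see :func:`build_regression`).
    """

    def __init__(self, records: pd.DataFrame, dt: float | None = None,
                 speed_exponents: dict | None = None):
        if dt is None:
            dt = records.attrs.get("dt")
        if dt is None:
            raise ValueError("frame interval dt is required")
        self.records = records.reset_index(drop=True)
        self.dt = float(dt)
        self.speed_exponents = {"wall": 1, "attract": 1, "align": 1}
        if speed_exponents:
            self.speed_exponents.update(speed_exponents)

    @classmethod
    def from_tracks(cls, tracks, tank: TankGeometry,
                    graph_method: str = "voronoi_shell1", knn_k: int | None = None,
                    fps: float | None = None, use_state_columns: bool = False,
                    wall_mode: str = "time_to_impact",
                    attract_saturation: float | None = None,
                    speed_exponents: dict | None = None) -> "SchoolingModel":
        """Build the regression from one track table or a list of replicates."""
        if isinstance(tracks, pd.DataFrame):
            tracks = [tracks]
        recs = []
        for s, tr in enumerate(tracks):
            kin = tr if isinstance(tr, Kinematics) else kinematics_from_track(
                tr, fps=fps, use_state_columns=use_state_columns)
            recs.append(build_regression(kin, tank, graph_method, knn_k,
                                         wall_mode, attract_saturation, series=s))
        rec = pd.concat(recs, ignore_index=True)
        rec.attrs.update(recs[0].attrs)
        return cls(rec, dt=recs[0].attrs["dt"], speed_exponents=speed_exponents)

    # -- fitting -------------------------------------------------------------

    def fit(self, mode: str = "pooled", method: str = "iv",
            discretization: str | None = None, active=None,
            x0: dict | None = None, bounds: dict | None = None,
            iv_lag: int = 2) -> SchoolingFitResult:
        """Estimate the behavioral constants.

        ``mode="pooled"`` shares the constants over all fish (per-fish mean
        speeds enter the speed scalings and τ = l/v̄); ``mode="per_fish"``
        returns a dict of independent per-fish fits.  ``method="iv"``
        (default) solves the lag-``iv_lag`` instrumented moment conditions
        (lag 2 is the smallest lag whose smoothing windows avoid the
        response's; under observation noise on positions, lag 3 also clears
        the shared endpoint frame); ``method="nls"`` minimizes the squared
        residuals with the chosen ``discretization`` gain.
        """
        if mode == "per_fish":
            out = {}
            for key, g in self.records.groupby(["series", "fish"]):
                sub = SchoolingModel(_copy_attrs(g, self.records), self.dt,
                                     self.speed_exponents)
                out[key] = sub.fit(mode="pooled", method=method,
                                   discretization=discretization,
                                   active=active, x0=x0, bounds=bounds,
                                   iv_lag=iv_lag)
            return out
        if mode != "pooled":
            raise ValueError(f"unknown mode {mode!r}")
        if method == "iv":
            if discretization is not None:
                raise ValueError("discretization applies to method='nls' only")
            disc = "iv"
        elif method == "nls":
            source = self.records.attrs.get("source", "positions")
            disc = discretization or ("filtered" if source == "positions" else "exact")
        else:
            raise ValueError(f"unknown method {method!r}")

        rec = self.records
        cols = _scaled_cols(rec, self.speed_exponents)
        structural = {k: bool(np.any(c != 0.0)) for k, c in cols.items()}
        if active is None:
            act = tuple(k for k in ("k_w", "k_p", "k_v") if structural[k]) + ("l",)
        else:
            act = tuple(active)
            for k in act:
                if k != "l" and not structural[k]:
                    raise ValueError(f"regressor column for {k} is identically zero")
            if "l" not in act:
                act = act + ("l",)
        act = tuple(k for k in _PARAM_NAMES if k in act)
        if len(rec) < 10 * len(act):
            raise ValueError("too few records for a stable fit "
                             f"(need >= {10 * len(act)}, got {len(rec)})")

        x0d = dict(_X0_DEFAULT)
        if x0:
            x0d.update(x0)
        bnd = dict(_BOUNDS_DEFAULT)
        if bounds:
            bnd.update(bounds)
        lo = [bnd[k][0] for k in act]
        hi = [bnd[k][1] for k in act]
        p0 = np.array([x0d[k] for k in act])

        if method == "iv":
            lags = (iv_lag,) if np.isscalar(iv_lag) else tuple(iv_lag)
            recT, recLs = _lag_pairs_multi(rec, self.dt, lags)
            colsT = _scaled_cols(recT, self.speed_exponents)
            blocks = []
            for recL in recLs:
                colsL = _scaled_cols(recL, self.speed_exponents)
                blocks += [colsL[k] for k in act if k != "l"]
                blocks.append(recL["omega"].to_numpy())
            Z = np.stack(blocks, axis=1)
            v = recT["v_bar"].to_numpy()
            omega = recT["omega"].to_numpy()
            domega = recT["domega"].to_numpy()
            nrec = len(recT)

            def residual_of(p):
                pd_ = dict(zip(act, p))
                g = _gain(self.dt * v / pd_["l"], disc)
                target = sum(pd_[k] * colsT[k] for k in act if k != "l")
                return domega - g * (target - omega)

            def objective(p):
                return Z.T @ residual_of(p) / nrec

            fit_rec = recT
        else:
            v = rec["v_bar"].to_numpy()
            omega = rec["omega"].to_numpy()
            domega = rec["domega"].to_numpy()

            def residual_of(p):
                pd_ = dict(zip(act, p))
                g = _gain(self.dt * v / pd_["l"], disc)
                target = sum(pd_[k] * cols[k] for k in act if k != "l")
                return domega - g * (target - omega)

            objective = residual_of
            fit_rec = rec

        res = optimize.least_squares(objective, p0, bounds=(lo, hi), method="trf",
                                     xtol=1e-12, ftol=1e-12, gtol=1e-12)
        if not res.success:  # multi-start with jittered inits
            rng = np.random.default_rng(0)
            for _ in range(3):
                p0j = np.clip(p0 * rng.lognormal(0, 0.5, len(p0)), lo, hi)
                alt = optimize.least_squares(objective, p0j, bounds=(lo, hi),
                                             method="trf", xtol=1e-12,
                                             ftol=1e-12, gtol=1e-12)
                if alt.success:
                    res = alt
                    break

        params = dict(zip(act, res.x))
        for k in _PARAM_NAMES:
            params.setdefault(k, np.nan)
        resid = residual_of(res.x)
        bse = self._bse(res, act, resid, method, Z if method == "iv" else None)
        at_bounds = tuple(k for k, xv, a, b in zip(act, res.x, lo, hi)
                          if xv - a < 1e-9 * (b - a) or b - xv < 1e-9 * (b - a))

        source = rec.attrs.get("source", "positions")
        sigma_by, sigma2_acc, n_acc = {}, 0.0, 0
        for key, g in fit_rec.assign(resid=resid).groupby(["series", "fish"]):
            r2 = float(np.var(g["resid"].to_numpy()))
            tau_f = params["l"] / g["v_bar"].iloc[0]
            s2f = _sigma2_from_resid(r2, tau_f, self.dt, disc, source)
            sigma_by[key] = float(np.sqrt(max(s2f, 0.0)))
            sigma2_acc += s2f * len(g)
            n_acc += len(g)
        sigma_hat = float(np.sqrt(max(sigma2_acc / max(n_acc, 1), 0.0)))

        return SchoolingFitResult(
            params=params, bse=bse, sigma_hat=sigma_hat, records=fit_rec,
            residuals=resid, dt=self.dt, mode="pooled", discretization=disc,
            active=act, speed_exponents=self.speed_exponents,
            success=bool(res.success), message=res.message, at_bounds=at_bounds,
            sigma_by_group=sigma_by, nfev=res.nfev)

    @staticmethod
    def _bse(res, act, resid, method, Z):
        try:
            if method == "iv":
                # just-identified GMM sandwich: G⁻¹ S G⁻ᵀ
                n = len(resid)
                G = res.jac
                Ze = Z * resid[:, None]
                S = Ze.T @ Ze / n**2
                Gi = np.linalg.inv(G)
                cov = Gi @ S @ Gi.T
            else:
                m, p = len(resid), len(act)
                s2 = float(resid @ resid) / max(m - p, 1)
                cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
            return dict(zip(act, np.sqrt(np.maximum(np.diag(cov), 0.0))))
        except np.linalg.LinAlgError:
            return {k: np.nan for k in act}


def _copy_attrs(g: pd.DataFrame, src: pd.DataFrame) -> pd.DataFrame:
    g = g.reset_index(drop=True)
    g.attrs.update(src.attrs)
    return g


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_params(records: pd.DataFrame, mode: str = "pooled", dt: float | None = None,
               speed_exponents: dict | None = None, **kwargs):
    """Fit the behavioral constants from a prebuilt regression table."""
    return SchoolingModel(records, dt=dt, speed_exponents=speed_exponents).fit(
        mode=mode, **kwargs)


def residual_diagnostics(fit: SchoolingFitResult) -> dict:
    return fit.residual_diagnostics()


def stimulus_response_curves(records: pd.DataFrame, fit: SchoolingFitResult,
                             **kwargs) -> dict:
    return fit.stimulus_response_curves(**kwargs)
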