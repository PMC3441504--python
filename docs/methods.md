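# Methods

## Model

Fish are modeled as self-propelled particles in a plane, each moving at a
constant tangential speed v while its angular velocity ω(t) — not its
heading — is the stochastic variable.  ω relaxes toward a stimulus-dependent
target ω* as an Ornstein–Uhlenbeck (OU) process,

    dω = −(1/τ) (ω − ω*) dt + σ dW,        τ = l / v,

so that trajectories are smooth and twice differentiable, matching the
persistent-turning-walker picture of real fish tracks.  The relaxation time
is parameterized through a persistence *length* l because the data this
model class was built for show the relaxation scaling with 1/v.  The target
combines three stimuli:

    ω*_i = f_W(θ_W, T) + (1/N_i) Σ_{j ∈ 𝒩_i} [ f_P(d_ij, ψ_ij) + f_V(φ_ij) ]

* **Wall avoidance** `f_W = k_w · cos(θ_W) · sign(θ_W) / T`, where θ_W is the
  signed angle between the heading and the outward normal at the point where
  the current heading ray meets the tank wall, and T = D_W / v is the time to
  impact.  The sign steers the fish to *increase* |θ_W| (away from a head-on
  approach) and the 1/T divergence guarantees containment without any
  reflecting boundary rule.  θ_W = 0 is a measure-zero symmetric
  configuration; the object API breaks the tie with a random sign, the
  simulation kernel with +1.  A `wall_mode="distance"` variant
  (k_w v^α_w cos θ_W sign θ_W / D_W) is available; in the default
  time-to-impact mode the speed dependence is already carried by 1/T and the
  wall speed exponent is ignored.
* **Attraction** `f_P = k_p v^α_p · d · sin ψ` — linear in the neighbor
  distance d (a small-distance expansion valid in a tank; an optional
  saturation `min(d, d_sat)` is provided for open-space scenarios), zero for
  a neighbor dead ahead, independent of the neighbor's own heading.
* **Alignment** `f_V = k_v v^α_v · sin φ` — leading Fourier term in the
  heading difference φ, independent of where the neighbor is.

The social terms are averaged (not summed) over the interaction
neighborhood 𝒩_i, so wall avoidance and the aggregate neighbor influence
keep the same relative weight at every group size.  The neighborhood is the
first shell of Voronoi neighbors (Delaunay adjacency, recomputed every
integration step), with all-to-all and K-nearest-neighbor graphs available
for comparison studies.  Collinear point sets, where no triangulation
exists, fall back to chain adjacency along the line; near-degenerate
(cocircular) configurations take whatever valid triangulation the
tessellation library returns.

Integration is Euler–Maruyama:

    ω ← ω + (dt/τ)(ω* − ω) + σ √dt ξ,   θ ← θ + ω dt,   x ← x + v (cos θ, sin θ) dt,

with one shared RNG stream consumed in fixed fish order for bit
reproducibility.  A position update that lands outside a bounded tank is
radially projected back to (1 − 10⁻⁶) R; such events are counted and a
warning is raised above 0.1% of steps — the model itself, via the diverging
wall term, is expected to keep fish inside, and the default parameter set
does so (zero projections in 10-minute runs at N = 1 and N = 10).

### Default constants

| parameter | symbol | default | units | role |
|---|---|---|---|---|
| wall strength | k_w | 5.0 | rad | wall-avoidance scale |
| persistence length | l | 0.2 | m | τ = l/v; OU relaxation |
| noise scale | σ | 0.8 | rad·s^−3/2 | Wiener increment scale |
| attraction | k_p | 1.0 | rad·m⁻¹ per (m/s)^α_p | positional term |
| alignment | k_v | 2.5 | rad per (m/s)^α_v | orientational term |
| speed exponents | α_w, α_p, α_v | 1 | — | v-scaling of each term |
| integration step | dt | 1/48 | s | divides the 12 fps frame interval |
| transient | — | 20 | s | discarded before measurement |

The defaults were calibrated once against three stated realism targets:
(a) no wall crossings at N = 1 and N = 10 anywhere in the 0.1–1.0 m/s design
speed range; (b) smooth, fish-like path curvature (ω SD ≈ 0.4–1 rad/s at
mid speeds); (c) the shoaling→schooling phenomenology — pairs nearly
aligned at high speed (P̄ ≳ 0.9), weakly ordered at low speed, with P̄
increasing in v.  Attraction is the effective symmetry breaker that unlocks
the metastable counter-circling state of a fast pair in a tank (anti-aligned
headings sit at the unstable zero of sin φ), which is why k_p matters for
(c) even though alignment dominates the moment-to-moment social response.
Pairs slower than ≈ 0.13 m/s occasionally touch the wall (≈ 0.2% of steps,
counted and warned); single fish and larger default-parameter groups do not.

The default dt = 1/48 s divides the 12 fps output frame interval exactly
(0.02 s does not); halving dt changes 120 s summary statistics by less than
their replicate spread.

## Synthetic experiment generator

`make_dataset` emulates a tank-experiment campaign: group sizes
{1, 2, 5, 10, 15, 30}, five replicates per size, 120 s measured at 12 frames/s
after a 20 s transient, tank radius 2.0 m, and a per-replicate common
swimming speed drawn uniformly from 0.1–1.0 m/s (fish within a replicate
swim at the same synchronized speed; the value varies between replicates).
Positions start uniform in the disc of 0.8 R with uniform headings and
ω = 0.  Optional isotropic Gaussian observation noise models tracking
error; an optional (2/N)^γ scaling of k_p and k_v imposes a known decrease
of interaction strength with group size for recovery studies.  The manifest
stores every seed and true parameter, and any replicate regenerates
bit-exactly from it.

What the generator does *not* emulate: speed fluctuations around the
per-replicate mean, identity swaps or occlusion gaps, body size and shape,
and any behavioral state changes over a trial.  Passing recovery tests
therefore demonstrates correctness of the inversion machinery under the
model's own assumptions, not robustness to every artifact of real tracking
data (frame gaps and position noise are covered; the rest is not).

## Parameter inversion

Headings are reconstructed as directions of successive position
displacements (chords), unwrapped; the angular velocity at frame n is the
difference of the two adjacent chord directions times the frame rate; the
heading used for stimulus evaluation at frame n is the direction of
x_{n+1} − x_{n−1}.  For uniform circular motion the chord construction is
exact.  No smoothing is applied by default; `smooth=(window, order)`
enables Savitzky–Golay position smoothing for noisy user data.  When a
track carries simulator state columns, `use_state_columns=True` uses them
directly (the exact-state path used to validate the optimizer itself).

One regression record per usable frame transition relates the response
Δω_n = ω_{n+1} − ω_n to the wall stimulus S_w = cos θ_W sign θ_W · v̄/D_W,
the neighbor-averaged attraction stimulus S_p = ⟨d sin ψ⟩, the alignment
stimulus S_v = ⟨sin φ⟩, and ω_n itself:

    Δω_n = g(Δt/τ) · (k_w S_w + k_p v̄^α_p S_p + k_v v̄^α_v S_v − ω_n) + ε_n,

with the track-mean speed v̄ entering the scalings and τ = l/v̄
(constant-speed assumption).

### Why the default fit is instrumented

The textbook discretization g = Δt/τ with ordinary least squares is
*inconsistent* on chord-reconstructed data, for two separate reasons:

1. **Smoothing.**  The chord-difference ω̃ is a triangle-kernel average of
   the true OU process over a 2Δt window.  The population lag-1 regression
   gain of such a filtered series is 1 − ρ₁(Δt/τ), not Δt/τ, and the
   discrepancy does **not** vanish as Δt → 0 — the naive fit overestimates
   τ by roughly +90% at any frame rate.  `ptwschool.oucorr` computes the
   exact second-order structure (variance attenuation and lag
   autocorrelations) of the kernel-averaged process from closed-form OU
   integrals.
2. **Shared noise.**  The social stimuli are measured from the *same*
   smoothed positions as the response, so regressor and disturbance share
   noise (correlated errors-in-variables), which inflates k_v and deflates
   τ by a further ~25%.

The default estimator (`method="iv"`) therefore solves moment conditions
instrumented with the regressors lagged two frames: the instruments'
smoothing windows are disjoint from the response's, and for disjoint windows
the OU covariances decay exactly like e^(−Δt/τ), so the moment conditions
hold with the exact-relaxation gain g = 1 − e^(−Δt/τ) and no kernel
correction.  σ² is recovered from the per-fish residual variance inverted
through the kernel-attenuated variance formula.  Standard errors come from
the just-identified GMM sandwich.  On the reference pipeline (5 pooled
N = 2 replicates, 120 s at 12 fps, 20 seeds) the median recovery errors are
about +1% (k_w), −9% (l), −6% (k_v) and +7% (σ).  The positional
coefficient k_p remains biased low (~−25%) and is by far the noisiest
estimate — in a tank the positional term never dominates alignment, so its
identification is intrinsically weak; this is a property of the confined
data, not of the optimizer.  For data with appreciable observation noise,
Savitzky–Golay smoothing plus `iv_lag=3` (instruments clear of the widened
smoothing window) keeps k_v recovery within ±20% at 2 mm position noise,
while l and σ are not meaningfully recoverable without an explicit
measurement-noise model.

`method="nls"` retains the plain least-squares fit with a choice of gain:
`"euler"` (Δt/τ — exact on full-rate simulator state output, and the form
under which noiseless data are recovered to optimizer tolerance),
`"exact"` (1 − e^(−Δt/τ), for point-sampled ω), and `"filtered"`
(1 − ρ₁(Δt/τ), which de-biases τ for an isolated fish but cannot remove the
shared-noise contamination of the social stimuli).

Fitting is bounded trust-region least squares (l ∈ [0.01, 5] m,
coefficients ∈ [0, 100], initial l = 0.2 m, coefficients 1), with three
jittered restarts on non-convergence and active bounds flagged.  Pooled
mode shares the constants across fish and replicates; per-fish mode fits
each series independently.  Structurally absent regressors (an unbounded
tank, or a single fish with no neighbors) are dropped from the active
parameter set automatically.

### Diagnostics

`residual_diagnostics` returns normal-QQ data, the QQ correlation (a
normality index; > 0.99 on well-specified synthetic fits) and the lag-1
residual autocorrelation.  Note that chord-difference observations overlap
in time, so even well-specified residuals carry structural autocorrelation;
the misspecification probe is the correlation between residuals and an
omitted stimulus, not residual whiteness.  `stimulus_response_curves`
subtracts the other two fitted components from the implied target response
and bins the remainder against each (speed-scaled) stimulus: under the
model each curve is a line through the origin with slope equal to the
fitted coefficient — the a-posteriori check of the functional ansatz.

## Collective statistics and prediction

Polarization P is the modulus of the mean heading unit vector; D is the
mean pairwise distance; NND the mean nearest-neighbor distance.
`predict_with_band` runs seeded replicate simulations, time-averages each
observable after the transient, and reports the across-run mean with
empirical 2.5–97.5% quantile bands (P is skewed near 1, so no normal
approximation), plus the interactions-off null model (wall only) as a
reference.  `knn_sweep` accumulates squared prediction errors of mean P and
D over a replicate set for each K of a K-nearest-neighbor coupling; with
`refit=True` the behavioral constants are first re-estimated from the
reference tracks under each knn:K stimulus graph (the full inversion
repeated per K).  The refit variant is the discriminating one: with the
true generating parameters held fixed the error curve over K is nearly
flat, whereas after per-K refits it is cleanly unimodal with its minimum
within ±1 of the mean first-shell Voronoi degree of the same
configurations, and K = 1 distinctly worst.  Because the pointwise argmin
of a shallow noisy curve wobbles by ±1–2, the sweep also reports
`best_k_smoothed`, the vertex of a quadratic fit to the error curve over
K ≥ 2 (K = 1 sits far off the quadratic regime) — the noise-robust estimate
of the minimum location used in the benchmark checks.

## Problem sizes used in the tests and acceptance script

Simulation-based checks are scaled to desk size as the package's own
standard benchmark: 20 seeds × 5 replicates for the headline recovery
medians, 20 (tests) or 12 (script) runs per speed for the speed–order
trend, 5 (tests) or 3 (script) replicates per group size for the group-size
effect, and 16–24 runs per K over 6–10 replicates at N ∈ {10, 15} for the
connectivity sweep.  The free-fish OU closed forms use a 10⁶-step run
(tests) or 6×10⁵ (script).

## Known limitations

* The estimator family assumes constant per-fish speed; strongly
  fluctuating speeds violate the τ = l/v̄ reduction.
* The linear attraction term cannot hold for sparse groups; open-space
  scenarios should enable the saturation distance.
* l and σ are not identifiable from noisy positions without modeling the
  measurement noise explicitly; only the interaction coefficients are
  robust there.
* Degenerate Voronoi configurations (≥ 4 cocircular points) take an
  arbitrary valid triangulation; tests avoid such fixtures.
* The wall functional form is the package's own default (divergent at
  contact, odd in θ_W); alternative published forms can be substituted via
  `wall_mode` or by editing the single site in `interactions`.
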