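# ptwschool

Agent-based simulation and statistical inversion of a fish-schooling model
for small groups in a circular tank, built for collective-behaviour
researchers who want to go from 2D trajectory tables to estimated
individual-level interaction rules and back to collective predictions.

## The model

Each fish is a persistent turning walker: a particle moving at constant
speed v whose *angular velocity* ω follows an Ornstein–Uhlenbeck process
relaxing toward a stimulus/response target,

    dω = −(1/τ)(ω − ω*) dt + σ dW,        τ = l / v,

    ω*_i = k_w cos(θ_W) sign(θ_W) / T  +  (1/N_i) Σ_{j∈𝒩_i} [ k_p v d_ij sin ψ_ij + k_v v sin φ_ij ]

with T = D_W/v the time to impact on the wall, (d, ψ, φ) the distance,
bearing and relative heading of a neighbor, and 𝒩_i the first shell of
Voronoi neighbors.  The five behavioral constants (k_w, l, σ, k_p, k_v) are
estimated from sampled trajectories by a discrete-time instrumented
least-squares regression of the turning response; collective observables
(polarization P, inter-individual distance D) validate the fitted model
against replicate simulation bands.  See `docs/methods.md` for the full
account, including why the naive Euler regression on finite-difference
angular velocities is badly biased and how the default estimator avoids it.

## Worked example

```python
import numpy as np
from ptwschool import (ExperimentDesign, ModelParams, SchoolingModel,
                       SimConfig, TankGeometry, make_dataset,
                       predict_with_band)

# generate an experiment-like synthetic dataset: five 2-fish replicates,
# 120 s at 12 fps in a 2 m-radius tank, known ground truth
design = ExperimentDesign(group_sizes=(2,), replicates=5, seed=0)
tracks, manifest = make_dataset(design, ModelParams())

# invert the model from the position tracks (pooled over replicates)
tank = TankGeometry(radius=2.0)
fit = SchoolingModel.from_tracks(list(tracks.values()), tank).fit()
print(fit.summary())

# predict the collective behaviour of a pair at 0.5 m/s with a 95% band
cfg = SimConfig(tank=tank, n_fish=2, params=ModelParams(), speeds=0.5)
band = predict_with_band(cfg, n_sims=20, seed=1)
print(f"mean P = {band.mean['P']:.3f}, 95% band = "
      f"({band.band['P'][0]:.3f}, {band.band['P'][1]:.3f})")
```

Output:

```
Schooling model fit
====================================================
mode: pooled   discretization: iv   records: 14350
converged: True   dt = 0.08333 s
----------------------------------------------------
 param     estimate      std err
   k_w       4.9984       0.0222  [rad]
     l      0.18213      0.00362  [m]
   k_p      0.77769       0.0417  [rad/m/s]
   k_v       2.3632       0.0388  [rad/s]
 sigma        0.844               [rad s^-3/2]
====================================================
mean P = 0.915, 95% band = (0.697, 0.996)
```

The generating constants were k_w = 5, l = 0.2 m, k_p = 1, k_v = 2.5,
σ = 0.8: the wall strength, persistence length, alignment weight and noise
scale are recovered to within a few percent; the positional weight k_p is
the least identifiable in a tank (confinement keeps attraction subordinate
to alignment — its standard error is correspondingly the widest), and the
polarization band says a pair at 0.5 m/s swims mostly aligned, with
occasional runs that lose synchronization (the band's low tail).

## Command line

The five verbs mirror the library:

```
ptwschool make-synthetic --design design.yaml --out data/
ptwschool simulate --config sim.yaml --seed 7 --out tracks.csv
ptwschool fit --tracks tracks.csv --tank-radius 2.0 --mode pooled --out fit.json
ptwschool stats --tracks tracks.csv --out stats.json
ptwschool validate --config sim.yaml --tracks tracks.csv --n-sims 100 --seed 1 --out report.json
```

Science parameters live in the YAML config (`tank:`, `model:`, `sim:`
blocks); every output directory gets a run manifest with the config hash,
seed and package version.

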