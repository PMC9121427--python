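# slipgait

A bipedal spring-loaded inverted pendulum (SLIP) template model with
**passive torsional-spring swing legs**, built to study how small rodent-like
bipeds (jerboas) transition between gaits across their whole speed range —
walking, hopping, skipping, symmetric running, and the formally defined
*asymmetrical running* gait with two unequal aerial phases.

## The model

A point mass m carries two massless linear-spring legs (rest length l₀,
stiffness k).  The state is q⃗ = (x, y, α_l, α_r): COM position plus leg
angles measured from the downward vertical (counterclockwise positive, so a
foot planted ahead of the COM has α > 0).  Everything is normalized by m,
l₀ and g.

* **Body** — ẍ = F_x/m, ÿ = F_y/m − g, where (F_x, F_y) sums the stance-leg
  spring forces k(l₀ − l_i) directed from each foot anchor to the COM.
* **Swing legs** — each hip carries a torsional spring of infinitesimal
  stiffness driving the leg toward its *neutral leg swing angle* (NLSA)
  φ_i at angular frequency ω:
  α̈_i = −(1/l₀)[ẍ cos α_i + (g + ÿ) sin α_i] − ω²(α_i − φ_i).
  In ballistic flight the coupling cancels and the leg is an exact harmonic
  oscillator about φ_i.
* **Stance legs** — an infinite-friction holonomic constraint pins the foot:
  x_c,i − x − y tan α_i = 0; differentiating twice yields the stance angular
  acceleration, and at touchdown the leg's angular velocity is reset to the
  unique value that keeps the new anchor stationary.

A gait is a periodic solution anchored at an apex of the COM height
(ẏ = 0).  With parameters fixed the model is conservative, so gaits form
one-dimensional families ("branches") as total energy varies.  The package
solves the stride as a boundary value problem — unknowns are the reduced
apex state plus the four touchdown/liftoff times and the stride time,
constrained by state periodicity and the foot-height conditions
y(t_i^j) = l₀ cos α_i(t_i^j) — and traces branches by pseudo-arclength
continuation.  Gait transitions appear either as Floquet-multiplier +1
bifurcations (hopping ↔ skipping: leg desynchronization) or as smooth
event-timing degeneracies where a touchdown and the opposite liftoff become
simultaneous (walking ↔ running, skipping ↔ asymmetrical running).

Nominal parameters follow the fitted animal data: k = 20 mg/l₀,
ω = 6.5 √(g/l₀), φ_l = φ_r = 0.

## Worked example

```python
import numpy as np
from slipgait import ModelParams, seed_symmetric_running, continue_branch
from slipgait import ContinuationOptions, locate_timing_degeneracy

p = ModelParams()                      # k=20, omega=6.5, phi=0
run = seed_symmetric_running(p, 2.0)   # symmetric running at apex speed 2
print(run.label.value, round(run.T, 4), np.round(run.s, 4))

br = continue_branch(run, +1, ContinuationOptions(max_points=150))
tp = locate_timing_degeneracy(br)[0]
print(tp.detail, round(tp.speed, 4))
```

prints

```
symmetric_running 1.0701 [ 0.9145  2.     -0.4953 -0.6085  0.4953 -0.6085]
walk<->run 1.1969
```

— a symmetric running gait with stride time T = 1.070 √(l₀/g) whose branch,
continued toward lower energy, terminates at the walking↔running timing
degeneracy at apex speed 1.197 √(g·l₀): below this speed the two aerial
phases vanish and the model walks; above, it runs.

The command line mirrors the library:

```sh
slipgait simulate --state 1.2,0,0,0,0,0          # zero-speed vertical hop
slipgait classify --times 0.3,0.6,0.3,0.6,1.0    # -> hopping
slipgait make-fixture --omega 6.49 --phi-l 0.17 --phi-r 0.10 \
    --speed 2.86 --noise-sigma 0.005 --seed 7 --out stride.csv
slipgait fit --trajectory stride.csv
```

Configuration files are flat `key=value` text (keys: k, omega, phi_l,
phi_r, rtol, atol, premature_tol, seed, frame_rate, noise_sigma, speed,
energy).  The default fixture frame rate, 40 frames per √(l₀/g),
corresponds to 500 fps video of an animal with l₀ ≈ 0.065 m.

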