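# epiexplore

Simulations of a curiosity-driven agent whose exploration behaviour is
decided by the *geometry of its internal world model*: a planar agent with
noisy sensors keeps Gaussian beliefs about object positions in its own
egocentric coordinates and always picks the move with the highest *epistemic
value* — the mutual information between the object's latent position and the
next observation. The package is for researchers in active inference and
embodied cognition who want a small, fully deterministic testbed for the
claim that perspective (Euclidean vs projective) alone can create or
suppress approach and exploration drives.

## The model

The agent's pose is a frame `R` (origin + orthonormal basis, third axis =
viewing direction). The world is seen through a chart:

- **Euclidean**: the rigid change of coordinates `φ_R` into the frame;
- **Projective**: `φᵖ_R = ρ ∘ φ_R`, where `ρ(x, y, z) = (x, y, z)/(γz + 1)`
  compresses depth like a focal lens (`γ ≥ 0`; `γ = 0` recovers the
  Euclidean case exactly). In homogeneous coordinates `φᵖ_R` is a 4×4
  matrix, and a move `m` induces the transition `ψ_m = φᵖ_{R^m} ∘ (φᵖ_R)⁻¹`.

Beliefs are Gaussians `Q_X = N(μ, Σ)` in internal coordinates; the sensor is
`P(Y|X=x) = N(x, ε²I)`. The epistemic value of a belief is

    C(Q_X) = I(X; Y) = ½ ln [ det(Σ_XX) det(Σ_YY) / det(Σ_{X,Y}) ],
    Σ_YY = Σ_XX + ε²I,

and the value of a move is `C(ψ_{m,*}Q_X)`, with the pushforward
`ψ_{m,*}Q_X` moment-matched to a Gaussian (exact for rigid maps,
Gauss–Hermite cubature or seeded Monte Carlo for projective ones).
Rigid maps leave `C` invariant, so a Euclidean agent has no reason to move;
the projective chart's Jacobian `|det ∇ρ| = (γz + 1)⁻⁴` grows as the depth
`z` of the believed object shrinks, so approaching magnifies the belief and
raises the value — the agent walks toward what it is uncertain about.

With several objects the agent also chooses which object to face; a narrow
field of view masks the rest. Hidden objects admit no observation, so their
beliefs are unchanged and contribute zero value (Pearl's update rule).
Observing an object shrinks its belief and with it the value of keeping
looking at it, which makes the agent swap targets — the γ×ε interplay sets
the swap rate and how often objects are reached.

## Worked example

```python
import numpy as np
from epiexplore import (
    GaussianBelief, GeometryConfig, SensorModel,
    compute_metrics, epistemic_value, run_one_object, run_two_object,
)
from epiexplore.experiments import one_object_config, two_object_config

belief = GaussianBelief.isotropic([0.0, 2.0], k=0.01)
print(f"epistemic value: {epistemic_value(belief, SensorModel(0.1)):.4f} nats")

for mode in (GeometryConfig.euclidean(), GeometryConfig.projective(1.0)):
    run = run_one_object(one_object_config(mode))
    print(f"{mode.mode:10s} final position {run.positions()[-1].round(3)}, "
          f"final distance {run.steps[-1].distances[0]:.3f}")

run = run_two_object(two_object_config(GeometryConfig.projective(1.0)))
print("two objects, gamma=1, eps=0.1:", compute_metrics(run))
```

prints

```
epistemic value: 0.6931 nats
euclidean  final position [0. 0.], final distance 2.000
projective final position [-0.071  1.971], final distance 0.077
two objects, gamma=1, eps=0.1: {'swap_count': 8, 'reach_count': 2}
```

The prior `N((0,2), 0.01·I)` with sensor noise `ε = 0.1` is worth exactly
`ln 2 ≈ 0.6931` nats per observation. Over 20 steps the Euclidean agent
never moves off its start (all moves are equally informative), while the
projective agent (γ = 1) walks the 2 units to the object and stops just
short of it. In the two-object scene the γ = 1 agent keeps its focus long
enough to reach both objects, swapping orientation 8 times in 40 steps;
at γ = 0 it swaps every step and reaches nothing.

A CLI mirrors these runs and writes CSV/JSON (and `--plot` PNGs):

```bash
epiexplore one-object --mode projective --gamma 1.0 --out-dir results
epiexplore direction-profile --out-dir results
epiexplore sweep --out-dir results
```

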