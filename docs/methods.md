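# Methods

## Model

A solid agent moves on a plane embedded in 3-D space (the plane `y = 0`;
planar points `(a, b)` are world points `(a, 0, b)`, so the second planar
coordinate is depth along the world z axis). Its pose is a right-handed
orthonormal frame whose third basis column is the viewing (depth) axis; by
convention the agent faces the object it is currently attending to, and
with several objects it keeps one belief per object, each expressed in the
frame that faces *that* object (as if imagining facing it). Frames are
re-orthonormalized by Gram–Schmidt on construction to absorb float drift.

Two groups can act on the internal model:

- **Euclidean**: internal coordinates are `φ_R(p) = Bᵀ(p − o)`; a move `m`
  induces the rigid transition `ψ_m = φ_{R^m} ∘ φ_R⁻¹`.
- **Projective**: the chart is `φᵖ_R = ρ ∘ φ_R` with
  `ρ(x, y, z) = (x, y, z)/(γz + 1)`. In homogeneous coordinates `φᵖ_R` is
  the product of `[[I, 0], [0 0 γ 1]]` with the affine block — its last row
  is γ times the affine map's depth row plus `(0, 0, 0, 1)`, so the
  homogeneous weight is `γ·(depth in the frame) + 1`. (The often-quoted
  literal last row `(0, 0, γ, 1)` is the special case of an axis-aligned
  frame; using it for general frames applies γ to the *world* z and produces
  qualitatively wrong behaviour.) Transitions are 4×4 matrix products,
  stored normalized so the largest-magnitude entry is 1.

Points with homogeneous weight `|w| ≤ 1e-12` lie on the projective horizon;
every operation raises a `HorizonError` there rather than returning
infinities, and a candidate move whose evaluation crosses the horizon is
scored `-inf` (rejected).

## Beliefs, sensor, epistemic value

Beliefs are Gaussians over internal coordinates (d = 2 in the planar
simulations; d = 3 is supported). The sensor is `P(Y|X=x) = N(x, ε²I)`.
The epistemic value `C(Q) = I(X; Y)` has the closed form
`½ ln(det Σ_XX · det Σ_YY / det Σ_{X,Y})`; since the joint determinant
factors as `det Σ_XX · ε^{2d}`, we evaluate the equivalent
`½ (ln det Σ_YY − 2d ln ε)`, which never underflows. Conditioning uses the
standard Gaussian formulas via linear solves (no explicit inverses), with
outputs symmetrized; a condition number above 1e12 on `Σ_YY` raises.

Epistemic value is *increasing* in the prior spread: a wider belief leaves
more to learn from one observation. The approach drive in the projective
mode comes from the transition map magnifying the belief (Jacobian
`|det ∇ρ| = (γz+1)⁻⁴` grows as depth z falls), not from shrinking it.

## Pushforward of beliefs

Moving pushes each belief through `ψ_m`; the image measure is approximated
by a Gaussian with matched mean and covariance:

- `closed_form_rigid` — exact for affine maps (`μ → Mμ + t`, `Σ → MΣMᵀ`);
  always used in Euclidean mode.
- `quadrature` (default) — tensor Gauss–Hermite cubature, order 11 per axis
  (121 nodes at d = 2). Deterministic, exact for polynomials of degree
  ≤ 21, and accurate to ~1e-6 for the mild nonlinearities that arise here
  (beliefs of scale √k ≈ 0.1 against horizon scales of order 1).
- `monte_carlo` — seeded draws (default n = 10,000), used as the
  independent cross-check of the cubature; bit-reproducible under a fixed
  seed.

Change of variables gives `μ_m = E_{x~Q}[ψ_m(x)]`, so sampling/cubature
needs no explicit Jacobian weighting. The quadrature path detects an
affine-equivalent projective matrix (last row proportional to
`(0, 0, 0, 1)`, e.g. γ = 0) and applies the exact closed form; this makes
the γ = 0 limit bit-identical to the Euclidean mode, so mirror-symmetric
ties in the two-object scene break the same way in both. Non-SPD image
covariances (float-level) are symmetrized and jittered by 1e-12 with a
warning.

A small discrete oracle (`ball_sensor_epistemic_value`) evaluates the
epistemic value under the uniform-ball sensor
`P(y|x) ∝ 1[‖x−y‖ ≤ ε]` by grid summation; it verifies the theory-level
properties (rigid invariance, growth under magnification) and is not a
production path.

## The exploration loop

Per step:

1. **Candidates**: idle plus eight translations of norm `step_norm` at 45°
   increments, rotated so one aims exactly at the faced object; with two
   objects, crossed with the orientation choices (18 candidates). A
   translation aiming at an object closer than `step_norm` is excluded (the
   agent cannot approach without overstepping); the object stays in the
   scene, so it can be left and re-approached.
2. **Scores**: each candidate's value is the sum over objects *visible from
   the post-move pose* of the epistemic value of that object's pushed
   belief; hidden objects contribute zero (Pearl). Orientation therefore
   matters only through the field-of-view mask.
3. **Selection**: argmax, ties to the lowest index. If every candidate
   sharing the winner's orientation is within `idle_tolerance = 1e-4` of
   that orientation's idle value, the differences are numerical noise and
   idle is selected. (With one orientation this is exactly the one-object
   rule.)
4. **Execution and update**: all beliefs are pushed through their
   transition maps; each visible object yields the noiseless observation
   `y = φ(ᵖ)_R(o)` (optionally with seeded `N(0, ε²I)` noise) and is
   conditioned on it; hidden beliefs are untouched.

Visibility is a closed condition: angle to the faced direction
`≤ fov_half_angle`. Planning is exactly one step ahead.

**Metrics.** A *swap* is a step whose faced object differs from the
previous step's (the run starts facing object 0). A *reach* is the first
step of an approach episode on which the distance to the faced object drops
below `step_norm`; leaving the zone re-arms the event.

## Defaults and why

| parameter        | default   | rationale                                             |
|------------------|-----------|-------------------------------------------------------|
| `k` (prior var)  | 0.01      | the two-object studies' printed value; reused for one-object runs |
| `ε`              | 0.1       | lower end of the studied range (most informative sensor) |
| `γ`              | 1.0       | upper end of the studied range (strongest focal effect) |
| `step_norm`      | 0.1       | ~20 steps to traverse the one-object distance of 2    |
| `n_steps`        | 20 / 40   | one-object / two-object run lengths                   |
| `fov_half_angle` | 20°       | in the two-object scene (objects ±33.7° from the start) exactly the faced object is visible |
| `idle_tolerance` | 1e-4      | the published numerical-noise band for idling         |
| cubature order   | 11        | exactness margin far beyond the needed accuracy at 121 nodes (d=2) |

The prior mean is the internal image of the true object position — the
agent knows where to look, not where the object is. The initial
orientation faces the first object.

## Experiments

- **Trajectory comparison**: agent (0,0), object (0,2), 20 steps, both
  geometries; the Euclidean run idles, the projective run approaches
  monotonically.
- **Direction profile**: a 20×20 grid of object positions over [−2, 2]²
  (grid extent and spacing are free choices; positions within 0.3 = 3
  step-norms of the agent are excluded so near-horizon geometry does not
  dominate). For each position the eight first-step translations are
  scored; values are binned by the eight translation angles relative to the
  object direction. Euclidean: flat at ln 2; projective: peaked at 0 rad,
  monotone in |angle|, mirror-symmetric.
- **Behaviour sweep**: the two-object scene over γ ∈ {0, 0.1, 0.25, 0.5,
  0.75, 1} × ε ∈ {0.1, 0.25, 0.5, 0.75, 1} (the published ranges; the
  sampled points are a choice), 40 steps, reporting swap and reach counts.
  Tests assert the trends on a coarser 4×3 subgrid: swaps non-increasing in
  γ and in ε.

## What the simulations do and do not show

The world is noiseless, static and fully scripted: objects do not move,
observations are exact chart images by default, and the action set is the
small discrete set above. Passing tests show that the *mechanism* —
geometry-induced magnification creating an approach drive, FOV masking plus
belief shrinkage creating oscillations — behaves as predicted under these
idealized conditions. They say nothing about noisy sensors with model
mismatch, continuous action spaces, moving objects, or learning of the
geometry itself, all of which are out of scope.

## Known limitations

- Points at infinity are not first-class: only chart points with valid
  homogeneous weight are supported; the horizon guard turns the measure-zero
  degenerate set into runtime errors.
- The Gaussian moment-matched pushforward is an approximation for
  projective maps; for beliefs wide enough to straddle the horizon it fails
  (by raising), rather than degrading silently.
- `d = 3` beliefs are supported by the inference layer but the agent loop
  is planar.
- The swap/reach phase diagram is sensitive to the FOV half-angle; the 20°
  default is one reasonable choice for the canonical scene, not a fitted
  value.
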