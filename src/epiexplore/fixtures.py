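"""Deterministic scene/belief generators and brute-force oracles.

The generators reproduce the two canonical scenes (one object at (0, 2);
two equidistant objects at (+-0.5, 0.75)) or draw seeded random ones.  The
oracles re-derive quantities the production code computes in closed form —
posterior moments by density products on a grid, mutual information by
Monte Carlo — and exist only for verification; nothing in the production
import path depends on them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import multivariate_normal

from .geometry import Frame, GeometryConfig, embed_plane, transition_map
from .inference import GaussianBelief

__all__ = [
    "FixtureSpec",
    "make_scene",
    "make_belief",
    "random_frame",
    "random_planar_transition",
    "grid_bayes_oracle",
    "mc_mutual_information_oracle",
]

_RANDOM_BOX = 2.0  # half-width of the box random scenes are drawn in


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a deterministic fixture (same spec -> identical output)."""

    seed: int = 0
    scene: str = "one_object_paper"
    belief: str = "isotropic_k"

    def __post_init__(self) -> None:
        if self.scene not in ("one_object_paper", "two_object_paper", "random"):
            raise ValueError(f"unknown scene preset {self.scene!r}")
        if self.belief not in ("isotropic_k", "random_spd"):
            raise ValueError(f"unknown belief preset {self.belief!r}")


def make_scene(spec: FixtureSpec):
    """Agent start and object positions for a scene preset.

    Random scenes draw the start and 1-3 objects uniformly in the box
    [-2, 2]^2, keeping objects at least 0.3 away from the start.
    """
    if spec.scene == "one_object_paper":
        return np.array([0.0, 0.0]), np.array([[0.0, 2.0]])
    if spec.scene == "two_object_paper":
        return np.array([0.0, 0.0]), np.array([[-0.5, 0.75], [0.5, 0.75]])
    rng = np.random.default_rng(spec.seed)
    start = rng.uniform(-_RANDOM_BOX, _RANDOM_BOX, size=2)
    objects = []
    n_objects = int(rng.integers(1, 4))
    while len(objects) < n_objects:
        candidate = rng.uniform(-_RANDOM_BOX, _RANDOM_BOX, size=2)
        if np.linalg.norm(candidate - start) >= 0.3:
            objects.append(candidate)
    return start, np.array(objects)


def make_belief(
    spec: FixtureSpec, mean=(0.0, 1.0), k: float = 0.01
) -> GaussianBelief:
    """Isotropic k*I belief, or a seeded random-SPD-covariance belief."""
    mean = np.asarray(mean, dtype=float)
    d = mean.shape[0]
    if spec.belief == "isotropic_k":
        return GaussianBelief.isotropic(mean, k)
    rng = np.random.default_rng(spec.seed)
    a = rng.standard_normal((d, d))
    cov = k * (a @ a.T + d * np.eye(d))
    return GaussianBelief(mean, cov)


def random_frame(rng: np.random.Generator, box: float = _RANDOM_BOX) -> Frame:
    """Frame at a random planar position facing a random planar target."""
    position = rng.uniform(-box, box, size=2)
    target = rng.uniform(-box, box, size=2)
    while np.linalg.norm(target - position) < 0.3:
        target = rng.uniform(-box, box, size=2)
    return Frame.facing(embed_plane(position), embed_plane(target))


def random_planar_transition(
    rng: np.random.Generator,
    geo: GeometryConfig,
    step_norm: float = 0.1,
):
    """Transition map of a random small move while facing a random object.

    Mirrors how transition maps arise in the simulations: the before and
    after frames both face the same object, the move is a translation of
    norm ``step_norm`` in a random direction.  Returns ``(map, frame_before,
    object_position)``.
    """
    position = rng.uniform(-1.0, 1.0, size=2)
    direction = rng.standard_normal(2)
    direction /= np.linalg.norm(direction)
    obj = position + rng.uniform(0.8, 2.0) * direction
    angle = rng.uniform(0, 2 * np.pi)
    move = step_norm * np.array([np.cos(angle), np.sin(angle)])
    f0 = Frame.facing(embed_plane(position), embed_plane(obj))
    f1 = Frame.facing(embed_plane(position + move), embed_plane(obj))
    return transition_map(f0, f1, geo), f0, obj


def grid_bayes_oracle(
    belief: GaussianBelief,
    epsilon: float,
    y,
    n_grid: int = 121,
    n_sigma: float = 6.0,
):
    """Posterior moments by brute-force density product on a grid.

    Tabulates prior(x) * N(y; x, eps^2 I) on a regular grid spanning
    ``n_sigma`` prior standard deviations around the prior mean (plus the
    observation), normalizes, and returns the empirical (mean, cov).
    Independent of the closed-form conditioning it is used to check.
    """
    y = np.asarray(y, dtype=float).reshape(belief.dim)
    if belief.dim != 2:
        raise NotImplementedError("the grid oracle is 2-D only")
    if n_sigma < 6.0:
        warnings.warn(
            "grid covers fewer than 6 prior standard deviations",
            RuntimeWarning,
            stacklevel=2,
        )
    sigma = np.sqrt(np.diag(belief.cov).max())
    centre = 0.5 * (belief.mean + y)
    half = n_sigma * sigma + 0.5 * np.abs(y - belief.mean).max()
    axes = [
        np.linspace(centre[i] - half, centre[i] + half, n_grid)
        for i in range(2)
    ]
    xs, ys = np.meshgrid(*axes, indexing="ij")
    grid = np.column_stack([xs.ravel(), ys.ravel()])
    prior = multivariate_normal(belief.mean, belief.cov).pdf(grid)
    likelihood = multivariate_normal(y, epsilon**2 * np.eye(2)).pdf(grid)
    density = prior * likelihood
    density /= density.sum()
    mean = density @ grid
    centered = grid - mean
    cov = (density[:, None] * centered).T @ centered
    return mean, cov


def mc_mutual_information_oracle(
    belief: GaussianBelief, epsilon: float, n: int = 100_000, seed: int = 0
) -> float:
    """Monte-Carlo estimate of I(X; Y) under the Gaussian generative pair.

    Samples (x, y) with x ~ Q and y | x ~ N(x, eps^2 I) and averages
    ln p(y|x) - ln p(y), with p(y) the exact Gaussian marginal
    N(mu, Sigma + eps^2 I).  Estimates the same mutual information as the
    closed-form epistemic value without using the determinant identity.
    """
    if n < 10_000:
        raise ValueError("use at least 10^4 samples")
    rng = np.random.default_rng(seed)
    d = belief.dim
    chol = np.linalg.cholesky(belief.cov)
    x = belief.mean + rng.standard_normal((n, d)) @ chol.T
    y = x + epsilon * rng.standard_normal((n, d))
    log_cond = multivariate_normal(np.zeros(d), epsilon**2 * np.eye(d)).logpdf(
        y - x
    )
    log_marg = multivariate_normal(
        belief.mean, belief.cov + epsilon**2 * np.eye(d)
    ).logpdf(y)
    return float(np.mean(log_cond - log_marg))
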