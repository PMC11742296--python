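"""Gaussian beliefs, the noisy sensor, and epistemic value.

The agent's belief about an object's position in its internal coordinates is
a multivariate normal Q_X = N(mu, Sigma).  The sensor is the Gaussian kernel
P(Y|X=x) = N(x, eps^2 I), so the joint distribution of (X, Y) is Gaussian
with covariance

    [[Sigma,          Sigma        ],
     [Sigma,  eps^2 I + Sigma      ]].

Epistemic value is the mutual information I(X; Y) of that joint — the
expected information gain about the object from one observation.  Moving
changes the belief by the pushforward through the frame-transition map
``psi_m``: exact for rigid maps, and approximated by a Gaussian with matched
mean and covariance (deterministic Gauss-Hermite cubature or seeded Monte
Carlo) for projective maps.

Objects hidden from view admit no observation: by Pearl's update rule the
belief is unchanged and the epistemic contribution is exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.spatial import cKDTree

from .geometry import (
    AffineMap,
    HorizonError,
    ProjectiveMap,
    embed_plane,
    plane_coords,
)

__all__ = [
    "GaussianBelief",
    "SensorModel",
    "PushforwardScheme",
    "joint_covariance",
    "condition_on_observation",
    "epistemic_value",
    "pushforward",
    "pearl_update_unobserved",
    "ball_sensor_epistemic_value",
]

_SYM_TOL = 1e-10
_COND_LIMIT = 1e12
_JITTER = 1e-12


@dataclass(frozen=True)
class GaussianBelief:
    """Mean and SPD covariance over internal coordinates (d = 2 or 3)."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float).reshape(-1)
        d = mean.shape[0]
        if d not in (2, 3):
            raise ValueError(f"belief dimension must be 2 or 3, got {d}")
        cov = np.asarray(self.cov, dtype=float).reshape(d, d)
        scale = max(1.0, float(np.abs(cov).max()))
        if np.abs(cov - cov.T).max() > _SYM_TOL * scale:
            raise ValueError("covariance is not symmetric")
        cov = 0.5 * (cov + cov.T)
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as err:
            raise ValueError("covariance is not positive definite") from err
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)

    @property
    def dim(self) -> int:
        return self.mean.shape[0]

    @classmethod
    def isotropic(cls, mean, k: float) -> "GaussianBelief":
        mean = np.asarray(mean, dtype=float).reshape(-1)
        return cls(mean, k * np.eye(mean.shape[0]))

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "cov": self.cov.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianBelief":
        return cls(np.array(d["mean"]), np.array(d["cov"]))


@dataclass(frozen=True)
class SensorModel:
    """Isotropic Gaussian observation noise, Sigma_{Y|X} = epsilon^2 I."""

    epsilon: float

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")


@dataclass(frozen=True)
class PushforwardScheme:
    """How the image measure of a belief under a map is moment-matched.

    ``closed_form_rigid`` is exact and applies only to affine maps;
    ``quadrature`` is a deterministic tensor Gauss-Hermite cubature of the
    image moments; ``monte_carlo`` draws ``n_samples`` seeded samples.
    """

    method: str = "quadrature"
    n_samples: int = 10_000
    seed: int = 0
    quadrature_order: int = 11

    def __post_init__(self) -> None:
        if self.method not in ("closed_form_rigid", "monte_carlo", "quadrature"):
            raise ValueError(f"unknown pushforward method {self.method!r}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if self.quadrature_order < 1:
            raise ValueError("quadrature_order must be positive")


def joint_covariance(belief: GaussianBelief, sensor: SensorModel) -> np.ndarray:
    """Covariance of the joint (X, Y) under the Gaussian sensor."""
    sxx = belief.cov
    syy = sxx + sensor.epsilon**2 * np.eye(belief.dim)
    return np.block([[sxx, sxx], [sxx, syy]])


def condition_on_observation(
    belief: GaussianBelief, sensor: SensorModel, y
) -> GaussianBelief:
    """Bayes update of the belief given an observation ``y``.

    mu' = mu + Sxx Syy^-1 (y - mu);  Sigma' = Sxx - Sxx Syy^-1 Sxx.
    """
    y = np.asarray(y, dtype=float).reshape(belief.dim)
    sxx = belief.cov
    syy = sxx + sensor.epsilon**2 * np.eye(belief.dim)
    if np.linalg.cond(syy) > _COND_LIMIT:
        raise np.linalg.LinAlgError("observation covariance is ill-conditioned")
    gain = np.linalg.solve(syy, sxx).T  # = Sxx @ Syy^-1 (both symmetric)
    mean = belief.mean + gain @ (y - belief.mean)
    cov = sxx - gain @ sxx
    return GaussianBelief(mean, 0.5 * (cov + cov.T))


def epistemic_value(belief: GaussianBelief, sensor: SensorModel) -> float:
    """Mutual information I(X; Y) in nats.

    Equal to (1/2) ln(det(Sxx) det(Syy) / det(Sigma_{X,Y})); since the joint
    determinant factors as det(Sxx) * eps^(2d) (Schur complement of the
    sensor noise), this reduces to the numerically stable
    (1/2) (ln det(Syy) - 2 d ln eps).
    """
    d = belief.dim
    syy = belief.cov + sensor.epsilon**2 * np.eye(d)
    sign, logdet = np.linalg.slogdet(syy)
    if sign <= 0:
        raise np.linalg.LinAlgError("observation covariance is not SPD")
    value = 0.5 * (logdet - 2.0 * d * np.log(sensor.epsilon))
    return max(float(value), 0.0)


def _apply_in_dim(mapping, points: np.ndarray, d: int) -> np.ndarray:
    """Apply a 3-D map to d-dimensional internal points (planar if d = 2)."""
    if d == 3:
        return mapping.apply(points)
    return plane_coords(mapping.apply(embed_plane(points)))


def _planar_restriction(affine: AffineMap) -> tuple[np.ndarray, np.ndarray]:
    """2x2 linear part and 2-shift of an affine map preserving y = 0."""
    if (
        max(
            abs(affine.linear[1, 0]),
            abs(affine.linear[1, 2]),
            abs(affine.linear[0, 1]),
            abs(affine.linear[2, 1]),
            abs(affine.shift[1]),
        )
        > 1e-9
    ):
        raise ValueError("affine map does not preserve the movement plane")
    idx = np.ix_([0, 2], [0, 2])
    return affine.linear[idx], affine.shift[[0, 2]]


def _repair_spd(cov: np.ndarray) -> np.ndarray:
    cov = 0.5 * (cov + cov.T)
    try:
        np.linalg.cholesky(cov)
        return cov
    except np.linalg.LinAlgError:
        warnings.warn(
            "pushforward covariance was not SPD; symmetrized and jittered",
            RuntimeWarning,
            stacklevel=3,
        )
        return cov + _JITTER * np.eye(cov.shape[0])


def _hermite_nodes(d: int, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Tensor-product Gauss-Hermite nodes/weights for N(0, I_d) expectations."""
    x, w = hermegauss(order)
    w = w / np.sqrt(2.0 * np.pi)
    grids = np.meshgrid(*([x] * d), indexing="ij")
    nodes = np.stack([g.ravel() for g in grids], axis=-1)
    wgrids = np.meshgrid(*([w] * d), indexing="ij")
    weights = np.prod(np.stack([g.ravel() for g in wgrids], axis=-1), axis=-1)
    return nodes, weights


def pushforward(
    belief: GaussianBelief,
    mapping,
    scheme: PushforwardScheme | None = None,
) -> GaussianBelief:
    """Moment-matched Gaussian approximation of the image measure psi_* Q.

    For affine maps with ``closed_form_rigid`` the result is exact
    (mu -> M mu + t, Sigma -> M Sigma M^T).  Otherwise the mean and
    covariance of psi(X), X ~ Q are integrated by cubature or estimated from
    seeded samples; the change-of-variables identity mu' = E_Q[psi(X)] means
    no Jacobian weighting is needed.

    Raises :class:`~epiexplore.geometry.HorizonError` if an evaluation point
    crosses the projective horizon.
    """
    scheme = scheme or PushforwardScheme()
    d = belief.dim
    if scheme.method == "closed_form_rigid":
        if not isinstance(mapping, AffineMap):
            raise TypeError("closed_form_rigid applies only to affine maps")
        if d == 3:
            lin, shift = mapping.linear, mapping.shift
        else:
            lin, shift = _planar_restriction(mapping)
        mean = lin @ belief.mean + shift
        cov = lin @ belief.cov @ lin.T
        return GaussianBelief(mean, _repair_spd(cov))

    if scheme.method == "quadrature" and isinstance(mapping, ProjectiveMap):
        # an affine-equivalent map (e.g. gamma = 0) has exactly Gaussian
        # image; use the closed form so Euclidean-limit ties stay exact
        affine = mapping.as_affine()
        if affine is not None:
            return pushforward(
                belief, affine, PushforwardScheme(method="closed_form_rigid")
            )
    chol = np.linalg.cholesky(belief.cov)
    if scheme.method == "quadrature":
        nodes, weights = _hermite_nodes(d, scheme.quadrature_order)
        points = belief.mean + nodes @ chol.T
        images = _apply_in_dim(mapping, points, d)
        mean = weights @ images
        centered = images - mean
        cov = (weights[:, None] * centered).T @ centered
    else:  # monte_carlo
        rng = np.random.default_rng(scheme.seed)
        draws = rng.standard_normal((scheme.n_samples, d))
        points = belief.mean + draws @ chol.T
        images = _apply_in_dim(mapping, points, d)
        mean = images.mean(axis=0)
        centered = images - mean
        cov = centered.T @ centered / (scheme.n_samples - 1)
    return GaussianBelief(mean, _repair_spd(cov))


def pearl_update_unobserved(
    belief: GaussianBelief,
) -> tuple[GaussianBelief, float]:
    """Belief update when no observation is possible (object out of view).

    The observation is totally uninformative, so the updated belief equals
    the prior and the epistemic contribution is exactly zero.
    """
    return belief, 0.0


def ball_sensor_epistemic_value(
    points, weights, spacing: float, epsilon: float
) -> float:
    """Epistemic value of a discrete 3-D belief under the uniform-ball sensor.

    Numerically evaluates -(3 / (4 pi eps^3)) * Integral dy Q(B_y^eps)
    ln Q(B_y^eps) by summation over a regular grid: ``points`` (N, 3) are the
    grid nodes, ``weights`` the belief mass at each node (summing to one) and
    ``spacing`` the grid step.  The grid must cover the belief's support plus
    an ``epsilon`` margin (weights may be zero there) so that the y-integral
    is not truncated.  This is a small theory-verification oracle, not a
    production path.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    w = np.asarray(weights, dtype=float).reshape(-1)
    if pts.shape[0] != w.shape[0]:
        raise ValueError("points and weights disagree in length")
    if not np.isclose(w.sum(), 1.0, atol=1e-8):
        raise ValueError("belief weights must sum to one")
    if not (epsilon > 0 and spacing > 0):
        raise ValueError("spacing and epsilon must be positive")
    if spacing > epsilon / 4:
        warnings.warn(
            "grid spacing exceeds epsilon/4; ball masses are poorly resolved",
            RuntimeWarning,
            stacklevel=2,
        )
    tree = cKDTree(pts)
    ball_mass = np.zeros(pts.shape[0])
    support = np.flatnonzero(w > 0)
    # accumulate each mass point into the balls (rows = y nodes) that contain it
    for i in support:
        for j in tree.query_ball_point(pts[i], epsilon + 1e-12):
            ball_mass[j] += w[i]
    mask = ball_mass > 0
    q = ball_mass[mask]
    integrand = -np.sum(q * np.log(q))
    return float(3.0 / (4.0 * np.pi * epsilon**3) * spacing**3 * integrand)
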