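"""Reference frames, rigid motions and the projective chart.

The agent is a solid moving on a plane inside a 3-D world.  Its pose is a
*frame*: an origin plus a right-handed orthonormal basis whose third column
is the forward (depth) axis and whose second column points up.  The internal
world model sees the world either through the affine change of coordinates
into the agent's frame (Euclidean case) or through that map followed by the
depth-compressing chart

    rho(x, y, z) = (x, y, z) / (gamma * z + 1),        gamma >= 0,

the restriction of a projective transformation of P3(R).  In homogeneous
coordinates the composite chart is a 4x4 matrix whose top 3x4 block is the
affine map and whose last row is (0, 0, gamma, 1).  A move of the agent
induces a transition map ``psi_m`` between the charts of the frames before
and after the move: a rigid motion in the Euclidean case, a projective
transformation otherwise.  ``gamma = 0`` recovers the Euclidean behaviour
exactly.

Points whose homogeneous weight vanishes (``gamma * z + 1 = 0``) sit on the
projective horizon; operations raise :class:`HorizonError` there instead of
returning infinities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Homogeneous weights with absolute value at or below this floor are treated
#: as lying on the projective horizon.
HORIZON_FLOOR = 1e-12

_UP = np.array([0.0, 1.0, 0.0])


class HorizonError(ValueError):
    """A point fell on or behind the projective horizon (gamma*z + 1 <= 0)."""


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.shape[-1] != 3:
        raise ValueError(f"expected 3-vectors, got shape {pts.shape}")
    return pts


def _gram_schmidt(basis: np.ndarray) -> np.ndarray:
    """Re-orthonormalize the columns of ``basis`` (classical Gram-Schmidt)."""
    q = np.empty_like(basis)
    for j in range(3):
        v = basis[:, j].copy()
        for i in range(j):
            v -= (q[:, i] @ basis[:, j]) * q[:, i]
        n = np.linalg.norm(v)
        if n < 1e-12:
            raise ValueError("frame basis is numerically singular")
        q[:, j] = v / n
    return q


@dataclass(frozen=True)
class Frame:
    """An origin plus a right-handed orthonormal basis.

    Basis columns are (right, up, forward); the forward axis is the depth
    direction used by the projective chart.  The basis is re-orthonormalized
    on construction to absorb floating-point drift; a left-handed basis is
    rejected.
    """

    origin: np.ndarray
    basis: np.ndarray

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        basis = np.asarray(self.basis, dtype=float).reshape(3, 3)
        if abs(np.linalg.det(basis)) < 1e-9:
            raise ValueError("frame basis is singular")
        basis = _gram_schmidt(basis)
        if np.linalg.det(basis) < 0:
            raise ValueError("frame basis must be right-handed (det = +1)")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "basis", basis)

    @property
    def right(self) -> np.ndarray:
        return self.basis[:, 0]

    @property
    def up(self) -> np.ndarray:
        return self.basis[:, 1]

    @property
    def forward(self) -> np.ndarray:
        return self.basis[:, 2]

    @classmethod
    def identity(cls) -> "Frame":
        return cls(np.zeros(3), np.eye(3))

    @classmethod
    def facing(
        cls,
        position,
        target,
        up=_UP,
        fallback_forward=(0.0, 0.0, 1.0),
    ) -> "Frame":
        """Frame at ``position`` whose forward axis points at ``target``.

        When ``target`` coincides with ``position`` the viewing direction is
        undefined and ``fallback_forward`` is used instead.
        """
        position = np.asarray(position, dtype=float).reshape(3)
        forward = np.asarray(target, dtype=float).reshape(3) - position
        norm = np.linalg.norm(forward)
        if norm < 1e-9:
            forward = np.asarray(fallback_forward, dtype=float).reshape(3)
            norm = np.linalg.norm(forward)
            if norm < 1e-9:
                raise ValueError("fallback forward direction is zero")
        forward = forward / norm
        up = np.asarray(up, dtype=float).reshape(3)
        right = np.cross(up, forward)
        rnorm = np.linalg.norm(right)
        if rnorm < 1e-9:
            raise ValueError("forward axis is parallel to the up axis")
        right = right / rnorm
        true_up = np.cross(forward, right)
        return cls(position, np.column_stack([right, true_up, forward]))

    def to_dict(self) -> dict:
        return {"origin": self.origin.tolist(), "basis": self.basis.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Frame":
        return cls(np.array(d["origin"]), np.array(d["basis"]))


@dataclass(frozen=True)
class AffineMap:
    """An invertible affine transformation ``x -> linear @ x + shift``."""

    linear: np.ndarray
    shift: np.ndarray

    def __post_init__(self) -> None:
        linear = np.asarray(self.linear, dtype=float).reshape(3, 3)
        shift = np.asarray(self.shift, dtype=float).reshape(3)
        if abs(np.linalg.det(linear)) < 1e-15:
            raise ValueError("affine map is singular")
        object.__setattr__(self, "linear", linear)
        object.__setattr__(self, "shift", shift)

    @classmethod
    def identity(cls) -> "AffineMap":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        pts = _as_points(points)
        return pts @ self.linear.T + self.shift

    __call__ = apply

    def compose(self, other: "AffineMap") -> "AffineMap":
        """Return ``self o other`` (``other`` applied first)."""
        return AffineMap(
            self.linear @ other.linear, self.linear @ other.shift + self.shift
        )

    def inverse(self) -> "AffineMap":
        inv = np.linalg.inv(self.linear)
        return AffineMap(inv, -inv @ self.shift)

    def is_rigid(self, tol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.linear.T @ self.linear, np.eye(3), atol=tol)
        )

    def as_homogeneous(self) -> np.ndarray:
        h = np.eye(4)
        h[:3, :3] = self.linear
        h[:3, 3] = self.shift
        return h

    def to_dict(self) -> dict:
        return {"linear": self.linear.tolist(), "shift": self.shift.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "AffineMap":
        return cls(np.array(d["linear"]), np.array(d["shift"]))


@dataclass(frozen=True)
class ProjectiveMap:
    """A projective transformation of 3-space, a 4x4 matrix up to scale.

    The stored representative is normalized so that its entry of largest
    magnitude equals one, which makes serialization reproducible; the induced
    point map is invariant to this choice.
    """

    H: np.ndarray

    def __post_init__(self) -> None:
        H = np.asarray(self.H, dtype=float).reshape(4, 4)
        if abs(np.linalg.det(H)) < 1e-300:
            raise ValueError("projective map is singular")
        H = H / H.flat[np.argmax(np.abs(H))]
        object.__setattr__(self, "H", H)

    @classmethod
    def identity(cls) -> "ProjectiveMap":
        return cls(np.eye(4))

    @classmethod
    def from_affine(cls, affine: AffineMap, gamma: float = 0.0) -> "ProjectiveMap":
        """Homogeneous matrix of ``rho_gamma o affine``.

        The product of the chart matrix [[I, 0], [0, 0, gamma, 1]] with the
        affine block [[M, t], [0, 1]]: the last row is gamma times the
        affine map's depth row plus (0, 0, 0, 1), so the homogeneous weight
        is ``gamma * depth-in-frame + 1``.  For an axis-aligned frame this
        reduces to the familiar last row (0, 0, gamma, 1).
        """
        h = affine.as_homogeneous()
        h[3, :] = float(gamma) * h[2, :]
        h[3, 3] += 1.0
        return cls(h)

    def as_affine(self, tol: float = 1e-12) -> AffineMap | None:
        """The equivalent affine map, or None if genuinely projective.

        A representative whose last row is proportional to (0, 0, 0, 1)
        induces an affine point map; the gamma = 0 chart is the main case.
        """
        h = self.H
        w = h[3, 3]
        if abs(w) <= HORIZON_FLOOR:
            return None
        if np.max(np.abs(h[3, :3])) > tol * abs(w):
            return None
        return AffineMap(h[:3, :3] / w, h[:3, 3] / w)

    def apply(self, points) -> np.ndarray:
        pts = _as_points(points)
        ones = np.ones(pts.shape[:-1] + (1,))
        image = np.concatenate([pts, ones], axis=-1) @ self.H.T
        w = image[..., 3]
        if np.any(np.abs(w) <= HORIZON_FLOOR):
            raise HorizonError("point maps to the projective horizon (|w| ~ 0)")
        return image[..., :3] / w[..., None]

    __call__ = apply

    def compose(self, other: "ProjectiveMap") -> "ProjectiveMap":
        """Return ``self o other`` (``other`` applied first)."""
        return ProjectiveMap(self.H @ other.H)

    def inverse(self) -> "ProjectiveMap":
        return ProjectiveMap(np.linalg.inv(self.H))

    def to_dict(self) -> dict:
        return {"H": self.H.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ProjectiveMap":
        return cls(np.array(d["H"]))


@dataclass(frozen=True)
class GeometryConfig:
    """Which group acts on the internal world model.

    ``mode="euclidean"`` uses rigid frame changes; ``mode="projective"`` uses
    the chart ``rho`` with parameter ``gamma``.  The projective mode with
    ``gamma = 0`` behaves identically to the Euclidean mode.
    """

    mode: str = "euclidean"
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("euclidean", "projective"):
            raise ValueError(f"unknown geometry mode {self.mode!r}")
        if not self.gamma >= 0:
            raise ValueError("gamma must be nonnegative")

    @classmethod
    def euclidean(cls) -> "GeometryConfig":
        return cls("euclidean", 0.0)

    @classmethod
    def projective(cls, gamma: float) -> "GeometryConfig":
        return cls("projective", float(gamma))

    def to_dict(self) -> dict:
        return {"mode": self.mode, "gamma": self.gamma}


def world_to_frame(frame: Frame) -> AffineMap:
    """Affine change of coordinates from world coordinates into ``frame``.

    A point on the frame's forward axis at distance ``d`` maps to
    ``(0, 0, d)``.
    """
    return AffineMap(frame.basis.T, -frame.basis.T @ frame.origin)


def rho(points, gamma: float) -> np.ndarray:
    """Depth-compressing chart ``p -> p / (gamma * z + 1)``."""
    pts = _as_points(points)
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    w = gamma * pts[..., 2] + 1.0
    if np.any(w <= HORIZON_FLOOR):
        raise HorizonError("point at or behind the projective horizon")
    return pts / w[..., None]


def rho_inverse(points, gamma: float) -> np.ndarray:
    """Inverse of :func:`rho`: ``q -> q / (1 - gamma * q_z)``."""
    pts = _as_points(points)
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    w = 1.0 - gamma * pts[..., 2]
    if np.any(w <= HORIZON_FLOOR):
        raise HorizonError("point at or behind the projective horizon")
    return pts / w[..., None]


def projective_chart(frame: Frame, gamma: float) -> ProjectiveMap:
    """Projective chart ``rho o world_to_frame(frame)`` as a 4x4 matrix."""
    return ProjectiveMap.from_affine(world_to_frame(frame), gamma=gamma)


def apply_projective(pmap: ProjectiveMap, points) -> np.ndarray:
    """Evaluate a projective map on points via homogeneous coordinates."""
    return pmap.apply(points)


def transition_map(
    frame_before: Frame, frame_after: Frame, geo: GeometryConfig
):
    """Map from before-frame internal coordinates to after-frame ones.

    Euclidean mode returns the rigid motion ``phi_after o phi_before^-1``;
    projective mode returns the projective transformation
    ``phi^p_after o (phi^p_before)^-1``.
    """
    if geo.mode == "euclidean":
        return world_to_frame(frame_after).compose(
            world_to_frame(frame_before).inverse()
        )
    before = projective_chart(frame_before, geo.gamma)
    after = projective_chart(frame_after, geo.gamma)
    return after.compose(before.inverse())


def jacobian_det_rho(points, gamma: float) -> np.ndarray:
    """|det| of the Jacobian of :func:`rho`: ``1 / (gamma * z + 1)**4``.

    Strictly increasing as the depth ``z`` decreases (for gamma > 0), which
    is what magnifies beliefs ahead of the agent as it approaches an object.
    """
    pts = _as_points(points)
    w = gamma * pts[..., 2] + 1.0
    if np.any(w <= HORIZON_FLOOR):
        raise HorizonError("point at or behind the projective horizon")
    return 1.0 / w**4


# -- planar world helpers -----------------------------------------------------
#
# The agent moves on the plane y = 0 (height fixed at zero); a planar point
# (a, b) embeds as the world point (a, 0, b), so the second planar coordinate
# is depth along the world's z axis.  Frames built with the default up vector
# preserve this plane, and internal planar coordinates are (lateral, depth).


def embed_plane(points2) -> np.ndarray:
    """Planar points (a, b) -> world points (a, 0, b)."""
    pts = np.asarray(points2, dtype=float)
    if pts.shape[-1] != 2:
        raise ValueError(f"expected 2-vectors, got shape {pts.shape}")
    out = np.zeros(pts.shape[:-1] + (3,))
    out[..., 0] = pts[..., 0]
    out[..., 2] = pts[..., 1]
    return out


def plane_coords(points3) -> np.ndarray:
    """World/internal 3-vectors -> planar (lateral, depth) coordinates."""
    pts = _as_points(points3)
    return pts[..., [0, 2]]


def apply_to_plane(mapping, points2) -> np.ndarray:
    """Apply an affine or projective map to planar points."""
    return plane_coords(mapping.apply(embed_plane(points2)))
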