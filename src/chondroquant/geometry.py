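"""Volume geometry and rigid transforms shared across modules.

World coordinates are patient-frame millimetres.  Voxel indices are
zero-based with the voxel *center* located exactly at the integer index
coordinate (NIfTI convention): ``world = direction @ diag(spacing) @ index
+ origin``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeGeometry", "RigidTransform"]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class VolumeGeometry:
    """Spatial calibration of a 3D image grid.

    Parameters
    ----------
    origin : (3,) world coordinates (mm) of voxel (0, 0, 0).
    spacing : (3,) voxel spacing (mm), strictly positive.
    direction : (3, 3) orthonormal direction-cosine matrix; columns are the
        world directions of the i, j, k index axes.
    dims : (3,) grid shape.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    dims: tuple[int, int, int]
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if d.shape != (3, 3):
            raise ValueError("direction must be a 3x3 matrix")
        if not np.allclose(d.T @ d, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix is not orthonormal")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if any(int(n) <= 0 for n in self.dims):
            raise ValueError("dims must be positive")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "dims", tuple(int(v) for v in self.dims))
        object.__setattr__(self, "direction", d)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VolumeGeometry):
            return NotImplemented
        return (
            self.origin == other.origin
            and self.spacing == other.spacing
            and self.dims == other.dims
            and bool(np.array_equal(self.direction, other.direction))
        )

    def __hash__(self) -> int:
        return hash((self.origin, self.spacing, self.dims, self.direction.tobytes()))

    def approx_equal(self, other: "VolumeGeometry", tol: float = 1e-9) -> bool:
        return (
            np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and self.dims == other.dims
            and np.allclose(self.direction, other.direction, atol=tol)
        )

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world homogeneous matrix."""
        a = np.eye(4)
        a[:3, :3] = self.direction @ np.diag(self.spacing)
        a[:3, 3] = self.origin
        return a

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx @ (self.direction @ np.diag(self.spacing)).T + np.asarray(self.origin)

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates of world points (no rounding)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        m = np.linalg.inv(self.direction @ np.diag(self.spacing))
        return (pts - np.asarray(self.origin)) @ m.T

    def grid_world_coords(self) -> np.ndarray:
        """World coordinates of every voxel center, shape dims + (3,)."""
        ii, jj, kk = np.meshgrid(
            np.arange(self.dims[0]),
            np.arange(self.dims[1]),
            np.arange(self.dims[2]),
            indexing="ij",
        )
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        return self.voxel_to_world(idx).reshape(self.dims + (3,))


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> rotation @ x + translation`` (mm)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if r.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(r.T @ r, np.eye(3), atol=_ORTHO_TOL * 1e3):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rotation=rt, translation=-rt @ self.translation)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m
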