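"""Condylar VOI atlas: registration plumbing, VOI partitioning of the bone
mesh, voxel-to-VOI assignment and depth-based layer splitting.

The six condylar VOIs are medial/lateral (side of the intercondylar plane)
crossed with anterior/central/posterior (fractional bands of each condyle's
anterior-posterior arc, thirds by default).  The anterior VOIs split
further into external/central/internal sub-VOIs by thirds of the condyle's
medial-lateral extent, external being farthest from the notch.  Boundary
placement is a declared convention, not taken from any reference anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import RigidTransform, VolumeGeometry
from .meshmodel import SurfaceMesh, SurfaceDistanceQuery

__all__ = [
    "AnatomicalFrame",
    "VOIPartition",
    "VoxelAssignment",
    "HeaderTransform",
    "header_transform",
    "partition_vois",
    "assign_voxels",
    "split_layers",
    "VOI_LABELS",
    "SUB_VOI_LABELS",
]

VOI_LABELS = ("Ma", "Mc", "Mp", "La", "Lc", "Lp")
SUB_VOI_LABELS = ("Mae", "Mac", "Mai", "Lae", "Lac", "Lai")


@dataclass(frozen=True)
class AnatomicalFrame:
    """Anatomical axes (unit vectors, patient mm) and the intercondylar plane.

    ``medial_sign`` selects which side of the plane (sign of the
    medial-lateral coordinate relative to ``notch_point``) is medial.
    """

    ap_axis: np.ndarray  # anterior direction
    ml_axis: np.ndarray  # medial-lateral direction
    pd_axis: np.ndarray  # proximal-distal direction
    notch_point: np.ndarray  # a point on the intercondylar plane
    medial_sign: int = -1

    def __post_init__(self) -> None:
        for name in ("ap_axis", "ml_axis", "pd_axis", "notch_point"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        m = np.column_stack([self.ap_axis, self.ml_axis, self.pd_axis])
        if abs(np.linalg.det(m)) < 1e-6:
            raise ValueError("degenerate anatomical frame: axes are collinear")
        for name in ("ap_axis", "ml_axis", "pd_axis"):
            v = getattr(self, name)
            n = np.linalg.norm(v)
            if n == 0:
                raise ValueError(f"{name} has zero length")
            object.__setattr__(self, name, v / n)
        if self.medial_sign not in (-1, 1):
            raise ValueError("medial_sign must be +1 or -1")

    def transformed(self, t: RigidTransform) -> "AnatomicalFrame":
        return AnatomicalFrame(
            ap_axis=t.rotation @ self.ap_axis,
            ml_axis=t.rotation @ self.ml_axis,
            pd_axis=t.rotation @ self.pd_axis,
            notch_point=t.apply(self.notch_point),
            medial_sign=self.medial_sign,
        )


@dataclass
class VOIPartition:
    """Per-bone-vertex VOI labels and anterior sub-labels.

    ``vertex_voi`` holds one of the six VOI labels per vertex;
    ``vertex_sub`` holds 'e'/'c'/'i' for anterior vertices, '' elsewhere.
    """

    vertex_voi: np.ndarray
    vertex_sub: np.ndarray

    def __post_init__(self) -> None:
        if self.vertex_voi.shape != self.vertex_sub.shape:
            raise ValueError("label arrays must align")
        bad = set(np.unique(self.vertex_voi)) - set(VOI_LABELS)
        if bad:
            raise ValueError(f"unknown VOI labels: {bad}")
        anterior = np.char.endswith(self.vertex_voi.astype(str), "a")
        subs = self.vertex_sub.astype(str)
        if np.any(subs[anterior] == "") or np.any(subs[~anterior] != ""):
            raise ValueError("sub-labels must cover exactly the anterior vertices")

    def sub_voi_labels(self) -> np.ndarray:
        """Full sub-VOI label (e.g. 'Mae') for anterior vertices, '' elsewhere."""
        out = np.char.add(self.vertex_voi.astype(str), self.vertex_sub.astype(str))
        anterior = np.char.endswith(self.vertex_voi.astype(str), "a")
        out[~anterior] = ""
        return out


@dataclass
class VoxelAssignment:
    """Masked-voxel VOI labels and relative depths."""

    indices: np.ndarray  # (N, 3) voxel indices
    voi: np.ndarray  # (N,) VOI label
    sub: np.ndarray  # (N,) anterior sub-label or ''
    depth: np.ndarray  # (N,) relative depth in [0, 1]
    n_dropped: int = 0

    def sub_voi_labels(self) -> np.ndarray:
        out = np.char.add(self.voi.astype(str), self.sub.astype(str))
        anterior = np.char.endswith(self.voi.astype(str), "a")
        out[~anterior] = ""
        return out


@dataclass(frozen=True)
class HeaderTransform:
    """Header-derived registration into a target acquisition frame.

    ``rigid`` maps source patient-frame mm into the target patient frame
    (identity when both headers share a frame of reference; a manual
    correction supplied in config is pre-composed).  The target's
    world-to-voxel map is exposed for voxel lookup.
    """

    rigid: RigidTransform
    target: VolumeGeometry

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.rigid.apply(points)

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        return self.target.world_to_voxel(points)


def header_transform(
    source: VolumeGeometry,
    target: VolumeGeometry,
    correction: RigidTransform | None = None,
) -> HeaderTransform:
    """Initial registration from acquisition headers.

    Both geometries carry origin/spacing/direction in a shared patient
    frame, so the header-derived rigid transform is the identity; a
    user-supplied ``correction`` (standing in for the interactive
    translate/rotate refinement) is composed on top.
    """
    if not isinstance(source, VolumeGeometry) or not isinstance(target, VolumeGeometry):
        raise TypeError("source and target must be VolumeGeometry")
    rigid = correction if correction is not None else RigidTransform.identity()
    return HeaderTransform(rigid=rigid, target=target)


def _arc_bands(values: np.ndarray, fractions: tuple[float, float]) -> np.ndarray:
    """Band index 0/1/2 by fractional position within [min, max] of values."""
    lo, hi = float(values.min()), float(values.max())
    span = hi - lo if hi > lo else 1.0
    frac = (values - lo) / span
    band = np.full(values.shape, 2, dtype=int)
    band[frac < fractions[1]] = 1
    band[frac < fractions[0]] = 0
    return band


def partition_vois(
    bone: SurfaceMesh,
    frame: AnatomicalFrame,
    ap_fractions: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0),
    ml_fractions: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0),
) -> VOIPartition:
    """Partition bone vertices into the six VOIs plus anterior sub-VOIs.

    Medial/lateral by side of the intercondylar plane; within each condyle,
    anterior/central/posterior by fractional bands of the anterior-
    posterior arc angle measured about the condyle centroid; anterior
    sub-VOIs by fractional bands of unsigned distance from the notch plane
    (internal nearest the notch).
    """
    if not (0 < ap_fractions[0] < ap_fractions[1] < 1):
        raise ValueError("ap_fractions must be increasing within (0, 1)")
    if not (0 < ml_fractions[0] < ml_fractions[1] < 1):
        raise ValueError("ml_fractions must be increasing within (0, 1)")
    v = bone.vertices
    s = (v - frame.notch_point) @ frame.ml_axis
    medial = (s * frame.medial_sign) > 0

    voi = np.empty(len(v), dtype="<U2")
    sub = np.full(len(v), "", dtype="<U1")
    ap_names = ("a", "c", "p")
    sub_names = ("i", "c", "e")  # ordered by growing distance from the notch

    for side_mask, prefix in ((medial, "M"), (~medial, "L")):
        if not side_mask.any():
            continue
        pts = v[side_mask]
        center = pts.mean(axis=0)
        u = pts - center
        norms = np.linalg.norm(u, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        u = u / norms
        alpha = np.arccos(np.clip(u @ frame.ap_axis, -1.0, 1.0))
        band = _arc_bands(alpha, ap_fractions)
        labels = np.array([prefix + ap_names[b] for b in band], dtype="<U2")
        voi[side_mask] = labels

        anterior = band == 0
        if anterior.any():
            d = np.abs(s[side_mask])
            ml_band = _arc_bands(d, ml_fractions)
            side_sub = np.full(len(pts), "", dtype="<U1")
            side_sub[anterior] = np.array([sub_names[b] for b in ml_band[anterior]])
            sub[side_mask] = side_sub

    return VOIPartition(vertex_voi=voi, vertex_sub=sub)


def assign_voxels(
    mask: np.ndarray,
    geometry: VolumeGeometry,
    bone: SurfaceMesh,
    cartilage: SurfaceMesh,
    partition: VOIPartition,
    transform: RigidTransform | None = None,
) -> VoxelAssignment:
    """Assign masked voxel centers a VOI label and a relative depth.

    The VOI is that of the nearest bone vertex (after mapping the meshes
    through ``transform`` into the voxel frame); relative depth is
    ``d_bone / (d_bone + d_cart)`` with exact surface distances.  Voxels
    where both distances vanish (depth undefined) are dropped and counted.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != tuple(geometry.dims):
        raise ValueError("mask shape does not match geometry dims")
    idx = np.argwhere(mask)
    if len(idx) == 0:
        return VoxelAssignment(
            indices=idx, voi=np.empty(0, "<U2"), sub=np.empty(0, "<U1"),
            depth=np.empty(0), n_dropped=0,
        )
    if len(partition.vertex_voi) != bone.n_vertices:
        raise ValueError("partition does not match bone mesh")
    t = transform if transform is not None else RigidTransform.identity()
    bone_t = bone.transformed(t)
    cart_t = cartilage.transformed(t)
    pts = geometry.voxel_to_world(idx)

    d_bone, _, _ = SurfaceDistanceQuery(bone_t).query(pts)
    d_cart, _, _ = SurfaceDistanceQuery(cart_t).query(pts)
    denom = d_bone + d_cart
    keep = denom > 0
    n_dropped = int((~keep).sum())
    depth = np.clip(d_bone[keep] / denom[keep], 0.0, 1.0)

    _, nearest = cKDTree(bone_t.vertices).query(pts[keep])
    return VoxelAssignment(
        indices=idx[keep],
        voi=partition.vertex_voi[nearest],
        sub=partition.vertex_sub[nearest],
        depth=depth,
        n_dropped=n_dropped,
    )


def split_layers(depths: np.ndarray) -> np.ndarray:
    """Label relative depths: 'deep' below 0.5, 'superficial' at or above.

    Depth 0 is the bone interface.  Values outside [0, 1] are rejected.
    """
    d = np.asarray(depths, dtype=float)
    if np.any(~np.isfinite(d)) or np.any(d < 0) or np.any(d > 1):
        raise ValueError("depths must lie in [0, 1]")
    return np.where(d < 0.5, "deep", "superficial").astype("<U11")
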