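"""Synthetic bi-condylar knee phantom.

Two spherical condyle lobes stand in for the femoral condyles: the bone
surface is a pair of icospheres, the cartilage surface is the bone surface
offset outward along vertex normals by a smooth thickness field, and the
cartilage volume carries a depth-dependent T2 field (low near bone, high
near the articular surface).  Multi-echo magnitude volumes are rendered
with the monoexponential signal model plus Rician noise, on the anisotropic
grid of the real T2 acquisition (0.313 x 0.446 x 3 mm by default).

Axis convention: x is medial-lateral (medial at negative x), y is
anterior-posterior (anterior positive), z proximal-distal.  The
intercondylar notch plane is x = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

from .geometry import VolumeGeometry
from .meshmodel import SurfaceMesh
from .relaxometry import MultiEchoVolume
from .voiatlas import AnatomicalFrame

__all__ = [
    "PhantomSpec",
    "ProgressionModel",
    "CartilageField",
    "Cohort",
    "KneeTimepoint",
    "icosphere",
    "make_condyle_models",
    "render_multiecho",
    "cartilage_mask",
    "default_geometry",
    "resolve_region_multiplier",
    "simulate_cohort",
    "simulate_measure_table",
    "phantom_frame",
    "TIMEPOINTS",
    "REGION_LABELS",
]

TIMEPOINTS = ("KL1", "KL2", "KL3")
REGION_LABELS = ("Ma", "Mc", "Mp", "La", "Lc", "Lp", "Mae", "Mac", "Mai", "Lae", "Lac", "Lai")

DEFAULT_ECHO_TIMES = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0)
DEFAULT_SPACING = (0.313, 0.446, 3.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, field and acquisition parameters of one synthetic knee."""

    condyle_radius_medial: float = 11.0
    condyle_radius_lateral: float = 11.0
    condyle_separation: float = 30.0  # center-to-center, mm
    thickness_base: float = 2.2  # mm
    thickness_ap_amplitude: float = 0.4  # mm, anterior-posterior modulation
    t2_deep: float = 32.0  # ms at the bone interface
    t2_superficial: float = 52.0  # ms at the articular surface
    s0: float = 400.0
    noise_sigma: float = 8.0  # Rician scale, signal units
    mesh_resolution: float = 0.8  # target edge length, mm
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    echo_times: tuple[float, ...] = DEFAULT_ECHO_TIMES
    tr: float = 2700.0  # ms, metadata only
    margin: float = 2.0  # mm padding around the cartilage bounding box
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condyle_radius_medial <= 0 or self.condyle_radius_lateral <= 0:
            raise ValueError("condyle radii must be positive")
        if self.thickness_base - abs(self.thickness_ap_amplitude) <= 0:
            raise ValueError("thickness field must be strictly positive everywhere")
        if self.t2_deep <= 0 or self.t2_superficial <= 0:
            raise ValueError("T2 field must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.mesh_resolution <= 0:
            raise ValueError("mesh_resolution must be positive")
        te = np.asarray(self.echo_times)
        if len(te) < 3 or np.any(np.diff(te) <= 0):
            raise ValueError("echo_times must be >= 3 and strictly ascending")
        tmax = self.thickness_base + abs(self.thickness_ap_amplitude)
        if self.condyle_separation <= (
            self.condyle_radius_medial + self.condyle_radius_lateral + 2 * tmax
        ):
            raise ValueError("condyles (with cartilage) must not intersect")

    @property
    def max_thickness(self) -> float:
        return self.thickness_base + abs(self.thickness_ap_amplitude)

    @property
    def centers(self) -> np.ndarray:
        """(2, 3) condyle centers, row 0 medial (negative x), row 1 lateral."""
        h = self.condyle_separation / 2.0
        return np.array([[-h, 0.0, 0.0], [h, 0.0, 0.0]])

    @property
    def radii(self) -> np.ndarray:
        return np.array([self.condyle_radius_medial, self.condyle_radius_lateral])


def phantom_frame() -> AnatomicalFrame:
    """Anatomical frame matching the phantom's axis convention."""
    return AnatomicalFrame(
        ap_axis=[0.0, 1.0, 0.0],
        ml_axis=[1.0, 0.0, 0.0],
        pd_axis=[0.0, 0.0, 1.0],
        notch_point=[0.0, 0.0, 0.0],
        medial_sign=-1,
    )


@dataclass(frozen=True)
class ProgressionModel:
    """Per-region multiplicative progression across severity timepoints.

    Multiplier dictionaries map timepoint -> region key -> factor; region
    keys may be a sub-VOI ('Mac'), a VOI ('Ma'), a compartment ('M'/'L') or
    'all'; the most specific match wins.  KL1 must be the identity.
    """

    t2_multipliers: dict = field(default_factory=dict)
    thickness_multipliers: dict = field(default_factory=dict)
    knee_t2_sd: float = 0.04  # lognormal sigma of knee-level T2 scale
    knee_thickness_sd: float = 0.04
    knee_radius_sd: float = 0.03
    timepoint_thickness_sd: float = 0.01  # per-visit segmentation variability
    timepoint_t2_sd: float = 0.012  # per-visit global T2 scale (rescan) variability
    measurement_sd: float = 0.015  # relative noise, table-only simulation
    months_between: tuple[float, float] = (18.0, 18.0)

    def __post_init__(self) -> None:
        for d in (self.t2_multipliers, self.thickness_multipliers):
            for tp, regions in d.items():
                if tp not in TIMEPOINTS:
                    raise ValueError(f"unknown timepoint {tp!r}")
                for key, mult in regions.items():
                    if mult <= 0:
                        raise ValueError("multipliers must be positive")
                    if tp == "KL1" and mult != 1.0:
                        raise ValueError("KL1 multipliers must be identity")
        if any(m <= 0 for m in self.months_between):
            raise ValueError("months_between must be positive")

    def months_at(self, timepoint: str) -> float:
        i = TIMEPOINTS.index(timepoint)
        return float(sum(self.months_between[:i]))

    @staticmethod
    def identity() -> "ProgressionModel":
        return ProgressionModel()


def _resolve_multiplier(mults: dict, voi: str, sub: str) -> float:
    """Most specific matching factor for a region, default 1."""
    for key in (voi + sub if sub else None, voi, voi[0], "all"):
        if key is not None and key in mults:
            return float(mults[key])
    return 1.0


def resolve_region_multiplier(model_mults: dict, timepoint: str, region: str) -> float:
    """Factor for a (possibly sub-) VOI label at a timepoint."""
    regions = model_mults.get(timepoint, {})
    voi, sub = (region[:2], region[2:]) if len(region) == 3 else (region, "")
    return _resolve_multiplier(regions, voi, sub)


# ---------------------------------------------------------------------------
# meshes

_PHI = (1.0 + np.sqrt(5.0)) / 2.0


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    v = np.array(
        [
            [-1, _PHI, 0], [1, _PHI, 0], [-1, -_PHI, 0], [1, -_PHI, 0],
            [0, -1, _PHI], [0, 1, _PHI], [0, -1, -_PHI], [0, 1, -_PHI],
            [_PHI, 0, -1], [_PHI, 0, 1], [-_PHI, 0, -1], [-_PHI, 0, 1],
        ],
        dtype=float,
    )
    v /= np.linalg.norm(v[0])
    f = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return v, f


def icosphere(subdivisions: int) -> SurfaceMesh:
    """Unit icosphere with one vertex pair exactly on the +/- y axis.

    Aligning a vertex pair with the anterior-posterior axis makes the
    vertex arc-angle range span exactly [0, pi], so fractional band edges
    computed from vertices coincide with the analytic ones.
    """
    verts, faces = _icosahedron()
    # rotate vertex 5 = (0, 1, phi)/|.| onto +y (its antipode lands on -y)
    target = verts[5]
    c = target[1]  # cos(angle to +y); rotation about x-axis
    s = target[2]
    rot = np.array([[1, 0, 0], [0, c, s], [0, -s, c]], dtype=float)
    verts = verts @ rot.T
    for _ in range(subdivisions):
        verts, faces = _subdivide(verts, faces)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    return SurfaceMesh(verts, faces)


def _subdivide(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cache: dict[tuple[int, int], int] = {}
    verts = [v for v in verts]

    def midpoint(i: int, j: int) -> int:
        key = (min(i, j), max(i, j))
        if key not in cache:
            m = (verts[i] + verts[j]) / 2.0
            verts.append(m / np.linalg.norm(m))
            cache[key] = len(verts) - 1
        return cache[key]

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
    return np.asarray(verts), np.asarray(new_faces, dtype=np.int64)


def _subdivisions_for(radius: float, target_edge: float) -> int:
    base_edge = 4.0 / np.sqrt(10.0 + 2.0 * np.sqrt(5.0))  # unit icosahedron
    n = int(np.ceil(np.log2(max(base_edge * radius / target_edge, 1.0))))
    return min(max(n, 1), 6)


# ---------------------------------------------------------------------------
# ground-truth fields


@dataclass
class CartilageField:
    """Analytic ground truth for one knee at one timepoint.

    Knows, for any world point: whether it lies in cartilage, its VOI and
    sub-VOI, its relative depth, its local thickness and its true T2.
    Band edges are taken from the generated bone mesh so that the truth
    convention matches :func:`chondroquant.voiatlas.partition_vois`.
    """

    centers: np.ndarray  # (2, 3), medial then lateral
    radii: np.ndarray  # (2,)
    thickness_base: float
    thickness_amp: float
    t2_deep: float
    t2_superficial: float
    ap_edges: np.ndarray  # (2, 2) arc-angle band edges per side
    ml_edges: np.ndarray  # (2, 2) notch-distance band edges per side
    t2_multipliers: dict = field(default_factory=dict)
    thickness_multipliers: dict = field(default_factory=dict)

    _AP = ("a", "c", "p")
    _SUB = ("i", "c", "e")

    def _side_u_rho(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        pts = np.atleast_2d(points)
        d = np.stack(
            [np.linalg.norm(pts - self.centers[i], axis=1) - self.radii[i] for i in (0, 1)]
        )
        side = np.argmin(np.abs(d), axis=0)
        rel = pts - self.centers[side]
        rho = np.linalg.norm(rel, axis=1)
        u = rel / np.where(rho[:, None] == 0, 1.0, rho[:, None])
        return side, u, rho

    def voi_at(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(VOI label, sub label) per point."""
        pts = np.atleast_2d(points)
        side, u, _ = self._side_u_rho(pts)
        alpha = np.arccos(np.clip(u[:, 1], -1.0, 1.0))
        prefix = np.where(side == 0, "M", "L")
        band = np.full(len(pts), 2)
        e = self.ap_edges[side]
        band[alpha < e[:, 1]] = 1
        band[alpha < e[:, 0]] = 0
        voi = np.char.add(prefix, np.array(self._AP)[band])
        sub = np.full(len(pts), "", dtype="<U1")
        anterior = band == 0
        if anterior.any():
            dist = np.abs(pts[:, 0])
            me = self.ml_edges[side]
            mlb = np.full(len(pts), 2)
            mlb[dist < me[:, 1]] = 1
            mlb[dist < me[:, 0]] = 0
            sub[anterior] = np.array(self._SUB)[mlb[anterior]]
        return voi.astype("<U2"), sub

    def _mult(self, mults: dict, voi: np.ndarray, sub: np.ndarray) -> np.ndarray:
        if not mults:
            return np.ones(len(voi))
        return np.array([_resolve_multiplier(mults, v, s) for v, s in zip(voi, sub)])

    def thickness_at(self, points: np.ndarray) -> np.ndarray:
        """Local cartilage thickness (mm) along the radial direction."""
        pts = np.atleast_2d(points)
        _, u, _ = self._side_u_rho(pts)
        voi, sub = self.voi_at(pts)
        base = self.thickness_base + self.thickness_amp * u[:, 1]
        return base * self._mult(self.thickness_multipliers, voi, sub)

    def mask_at(self, points: np.ndarray) -> np.ndarray:
        """True where the point lies inside the cartilage shell."""
        pts = np.atleast_2d(points)
        side, _, rho = self._side_u_rho(pts)
        r = self.radii[side]
        return (rho >= r) & (rho <= r + self.thickness_at(pts))

    def depth_at(self, points: np.ndarray) -> np.ndarray:
        """Relative depth: 0 at bone, 1 at the articular surface."""
        pts = np.atleast_2d(points)
        side, _, rho = self._side_u_rho(pts)
        r = self.radii[side]
        t = self.thickness_at(pts)
        return np.clip((rho - r) / t, 0.0, 1.0)

    def t2_at(self, points: np.ndarray) -> np.ndarray:
        """True T2 (ms): linear in depth, scaled by the VOI multiplier."""
        depth = self.depth_at(points)
        voi, sub = self.voi_at(np.atleast_2d(points))
        base = self.t2_deep + (self.t2_superficial - self.t2_deep) * depth
        return base * self._mult(self.t2_multipliers, voi, sub)


def _band_edges(values: np.ndarray, fractions=(1.0 / 3.0, 2.0 / 3.0)) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    return np.array([lo + fractions[0] * (hi - lo), lo + fractions[1] * (hi - lo)])


def make_condyle_models(
    spec: PhantomSpec,
    t2_multipliers: dict | None = None,
    thickness_multipliers: dict | None = None,
) -> tuple[SurfaceMesh, SurfaceMesh, np.ndarray, CartilageField]:
    """Build bone and cartilage meshes plus the analytic ground-truth field.

    The cartilage mesh is the bone mesh offset outward along (exact
    spherical) vertex normals by the thickness field.  Returns
    ``(bone, cartilage, truth_thickness, field)`` with ``truth_thickness``
    aligned to the bone vertices.
    """
    parts_bone, parts_cart = [], []
    ap_edges, ml_edges = [], []
    for i in range(2):
        r = spec.radii[i]
        unit = icosphere(_subdivisions_for(r, spec.mesh_resolution))
        verts = unit.vertices * r + spec.centers[i]
        parts_bone.append(SurfaceMesh(verts, unit.faces))
        alpha = np.arccos(np.clip(unit.vertices[:, 1], -1.0, 1.0))
        ap_edges.append(_band_edges(alpha))
        ml_edges.append(_band_edges(np.abs(verts[:, 0])))
    bone = SurfaceMesh.concatenate(parts_bone)

    fld = CartilageField(
        centers=spec.centers,
        radii=spec.radii,
        thickness_base=spec.thickness_base,
        thickness_amp=spec.thickness_ap_amplitude,
        t2_deep=spec.t2_deep,
        t2_superficial=spec.t2_superficial,
        ap_edges=np.asarray(ap_edges),
        ml_edges=np.asarray(ml_edges),
        t2_multipliers=dict(t2_multipliers or {}),
        thickness_multipliers=dict(thickness_multipliers or {}),
    )

    truth = fld.thickness_at(bone.vertices)
    if np.any(truth <= 0):
        raise ValueError("thickness field is non-positive at a bone vertex")
    # spherical normals are exact: offset radially from each condyle center
    offset = 0
    cart_parts = []
    for i in range(2):
        part = parts_bone[i]
        n = part.n_vertices
        u = (part.vertices - spec.centers[i]) / spec.radii[i]
        cart_verts = part.vertices + u * truth[offset : offset + n, None]
        cart_parts.append(SurfaceMesh(cart_verts, part.faces))
        offset += n
    cartilage = SurfaceMesh.concatenate(cart_parts)
    return bone, cartilage, truth, fld


# ---------------------------------------------------------------------------
# rendering


def default_geometry(spec: PhantomSpec, thickness_headroom: float = 1.0) -> VolumeGeometry:
    """Grid covering the cartilage bounding box plus a margin."""
    reach = spec.radii + spec.max_thickness * max(thickness_headroom, 1.0)
    lo = np.min(spec.centers - reach[:, None], axis=0) - spec.margin
    hi = np.max(spec.centers + reach[:, None], axis=0) + spec.margin
    spacing = np.asarray(spec.spacing)
    dims = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 2)
    return VolumeGeometry(origin=tuple(lo), spacing=tuple(spacing), dims=tuple(dims))


def render_multiecho(
    spec: PhantomSpec,
    fld: CartilageField,
    geometry: VolumeGeometry | None = None,
    rng: np.random.Generator | None = None,
) -> MultiEchoVolume:
    """Render the multi-echo magnitude volumes.

    Cartilage voxels follow ``S0 * exp(-TE / T2)``; background voxels carry
    zero signal.  With ``noise_sigma > 0`` every voxel magnitude is
    Rician-corrupted (magnitude of the signal plus complex Gaussian noise),
    so background magnitudes are Rayleigh distributed.
    """
    geom = geometry if geometry is not None else default_geometry(spec)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    pts = geom.grid_world_coords().reshape(-1, 3)
    mask = fld.mask_at(pts)
    t2 = fld.t2_at(pts[mask])
    te = np.asarray(spec.echo_times)
    n_e = len(te)
    signals = np.zeros((n_e, len(pts)))
    signals[:, mask] = spec.s0 * np.exp(-np.outer(te, 1.0 / t2))
    if spec.noise_sigma > 0:
        re = signals + rng.normal(0.0, spec.noise_sigma, signals.shape)
        im = rng.normal(0.0, spec.noise_sigma, signals.shape)
        signals = np.hypot(re, im)
    return MultiEchoVolume(
        echo_times=te, signals=signals.reshape((n_e,) + geom.dims), geometry=geom
    )


def cartilage_mask(fld: CartilageField, geometry: VolumeGeometry) -> np.ndarray:
    """Boolean ground-truth cartilage mask on a grid."""
    pts = geometry.grid_world_coords().reshape(-1, 3)
    return fld.mask_at(pts).reshape(geometry.dims)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class KneeTimepoint:
    knee: int
    timepoint: str
    months: float
    spec: PhantomSpec
    bone: SurfaceMesh
    cartilage: SurfaceMesh
    truth_thickness: np.ndarray
    field: CartilageField
    volume: MultiEchoVolume


@dataclass
class Cohort:
    knees: list  # list of {timepoint: KneeTimepoint}
    truth_table: pd.DataFrame  # knee, timepoint, months, region, true_t2, true_thickness


def _perturbed_spec(spec: PhantomSpec, model: ProgressionModel, rng: np.random.Generator) -> PhantomSpec:
    t2_f = float(np.exp(rng.normal(0.0, model.knee_t2_sd)))
    th_f = float(np.exp(rng.normal(0.0, model.knee_thickness_sd)))
    r_f = float(np.exp(rng.normal(0.0, model.knee_radius_sd)))
    return replace(
        spec,
        t2_deep=spec.t2_deep * t2_f,
        t2_superficial=spec.t2_superficial * t2_f,
        thickness_base=spec.thickness_base * th_f,
        thickness_ap_amplitude=spec.thickness_ap_amplitude * th_f,
        condyle_radius_medial=spec.condyle_radius_medial * r_f,
        condyle_radius_lateral=spec.condyle_radius_lateral * r_f,
    )


def simulate_cohort(
    n_knees: int,
    spec: PhantomSpec,
    model: ProgressionModel,
    seed: int | None = None,
    render: bool = True,
) -> Cohort:
    """Simulate a longitudinal cohort of progressing knees.

    Each knee perturbs the template spec (knee-level lognormal scales) and
    is imaged at the three severity timepoints with the model's per-region
    multipliers applied to the T2 and thickness fields.  Randomness derives
    from ``seed`` through per-knee / per-timepoint substreams keyed by
    ``(seed, knee, timepoint)``, so cohorts are reproducible under
    reordering.  ``render=False`` skips volume rendering (geometry and
    ground truth only).
    """
    if n_knees < 2:
        raise ValueError("need at least 2 knees")
    base_seed = spec.seed if seed is None else seed
    knees = []
    rows = []
    for k in range(n_knees):
        knee_rng = np.random.default_rng([base_seed, k])
        kspec = _perturbed_spec(spec, model, knee_rng)
        geom = default_geometry(kspec, thickness_headroom=_max_mult(model.thickness_multipliers))
        tps = {}
        for it, tp in enumerate(TIMEPOINTS):
            t2m = model.t2_multipliers.get(tp, {})
            thm = model.thickness_multipliers.get(tp, {})
            # per-visit thickness perturbation stands in for segmentation
            # variability; T2 measurement noise comes from the Rician render
            seg_rng = np.random.default_rng([base_seed, k, it, 1])
            seg_f = float(np.exp(seg_rng.normal(0.0, model.timepoint_thickness_sd)))
            t2_f = float(np.exp(seg_rng.normal(0.0, model.timepoint_t2_sd)))
            tspec = replace(
                kspec,
                thickness_base=kspec.thickness_base * seg_f,
                thickness_ap_amplitude=kspec.thickness_ap_amplitude * seg_f,
                t2_deep=kspec.t2_deep * t2_f,
                t2_superficial=kspec.t2_superficial * t2_f,
            )
            bone, cart, truth_th, fld = make_condyle_models(
                tspec, t2_multipliers=t2m, thickness_multipliers=thm
            )
            vol = None
            if render:
                vol = render_multiecho(
                    tspec, fld, geometry=geom, rng=np.random.default_rng([base_seed, k, it])
                )
            tps[tp] = KneeTimepoint(
                knee=k, timepoint=tp, months=model.months_at(tp), spec=tspec,
                bone=bone, cartilage=cart, truth_thickness=truth_th, field=fld, volume=vol,
            )
            mid_t2 = 0.5 * (tspec.t2_deep + tspec.t2_superficial)
            voi_v, sub_v = fld.voi_at(bone.vertices)
            full = np.char.add(voi_v, sub_v)
            for region in REGION_LABELS:
                t2_mult = resolve_region_multiplier(model.t2_multipliers, tp, region)
                th_mult = resolve_region_multiplier(model.thickness_multipliers, tp, region)
                if len(region) == 3:
                    sel = full == region
                else:
                    sel = voi_v == region
                side = 0 if region[0] == "M" else 1
                base_th = (
                    tspec.thickness_base
                    + tspec.thickness_ap_amplitude
                    * float(np.mean((bone.vertices[sel] - tspec.centers[side])[:, 1]))
                    / tspec.radii[side]
                )
                rows.append(
                    {
                        "knee": k,
                        "timepoint": tp,
                        "months": model.months_at(tp),
                        "region": region,
                        "true_t2": mid_t2 * t2_mult,
                        "true_thickness": base_th * th_mult,
                    }
                )
        knees.append(tps)
    table = pd.DataFrame(rows)
    return Cohort(knees=knees, truth_table=table)


def _max_mult(mults: dict) -> float:
    vals = [v for regions in mults.values() for v in regions.values()]
    return max(vals + [1.0])


def simulate_measure_table(
    n_knees: int,
    model: ProgressionModel,
    seed: int,
    base_values: dict | None = None,
) -> pd.DataFrame:
    """Lightweight cohort simulation at the measure-table level.

    Skips imaging entirely: per-knee, per-timepoint measure values are the
    base value times the knee's lognormal scale, the model's region
    multiplier, and a relative measurement-noise factor.  Long format:
    knee, timepoint, months, measure, value.  Useful for statistical
    calibration experiments where rendering would dominate the cost.
    """
    if n_knees < 2:
        raise ValueError("need at least 2 knees")
    base = dict(base_values or {})
    default_bases = {"T2": 42.0, "thickness": 2.2}
    rows = []
    for k in range(n_knees):
        knee_rng = np.random.default_rng([seed, k, 10_000])
        scales = {
            "T2": float(np.exp(knee_rng.normal(0.0, model.knee_t2_sd))),
            "thickness": float(np.exp(knee_rng.normal(0.0, model.knee_thickness_sd))),
        }
        for it, tp in enumerate(TIMEPOINTS):
            rng = np.random.default_rng([seed, k, it])
            for family, mults in (("T2", model.t2_multipliers), ("thickness", model.thickness_multipliers)):
                for region in REGION_LABELS:
                    mult = resolve_region_multiplier(mults, tp, region)
                    b = base.get(f"{region}_{family}", default_bases[family])
                    noise = float(np.exp(rng.normal(0.0, model.measurement_sd)))
                    rows.append(
                        {
                            "knee": k,
                            "timepoint": tp,
                            "months": model.months_at(tp),
                            "measure": f"{region}_{family}",
                            "value": b * scales[family] * mult * noise,
                        }
                    )
    return pd.DataFrame(rows)
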