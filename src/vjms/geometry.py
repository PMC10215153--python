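"""Parametric synthetic TKA geometry.

Builds a surrogate right-knee geometry set: a single-radius cruciate-retaining
(CR) femoral component with two toroidal condyles, a dished UHMWPE insert on a
tibial tray, and femur/tibia bone surrogates including the proximal-medial
tibial bulge the superficial MCL wraps around.

World frame (right knee, millimetres):
    x = anterior, y = proximal (superior), z = lateral.
The joint line sits at y = 0: the femoral condyles' distal-most points and the
insert dish bottoms coincide there at the reference pose (full extension).
The femoral flexion axis runs along z through ``(0, condyle_radius, 0)``.

External rotation of the femoral component is positive for placement
conditions and, for a right knee, maps anterior toward lateral (the medial
condyle moves anteriorly, opening the medial flexion gap).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "SurfaceMesh",
    "ImplantParams",
    "AlignmentCondition",
    "WrapSphere",
    "KneeGeometry",
    "CONDITIONS",
    "make_knee_geometry",
    "compute_pca",
    "align_component",
    "place_component",
    "rotation_about",
    "save_geometry",
    "load_geometry",
]


class GeometryError(ValueError):
    """Raised when a construction or axis computation fails."""


@dataclass
class SurfaceMesh:
    """A labelled triangulated surface (vertices in mm)."""

    mesh: trimesh.Trimesh
    label: str
    metadata: dict = field(default_factory=dict)

    @property
    def vertices(self) -> np.ndarray:
        return np.asarray(self.mesh.vertices)

    @property
    def faces(self) -> np.ndarray:
        return np.asarray(self.mesh.faces)

    def transformed(self, matrix: np.ndarray) -> "SurfaceMesh":
        m = self.mesh.copy()
        m.apply_transform(matrix)
        meta = dict(self.metadata)
        R, t = matrix[:3, :3], matrix[:3, 3]
        if "condyles" in meta:
            meta["condyles"] = [
                {**c,
                 "center": tuple(R @ np.asarray(c["center"]) + t),
                 "axis": tuple(R @ np.asarray(c.get("axis", (0, 0, 1.0)))),
                 "u1": tuple(R @ np.asarray(c.get("u1", (0, -1.0, 0)))),
                 "u2": tuple(R @ np.asarray(c.get("u2", (-1.0, 0, 0))))}
                for c in meta["condyles"]]
        for key in ("fe_axis_point", "center"):
            if key in meta:
                meta[key] = tuple(R @ np.asarray(meta[key]) + t)
        if "fe_axis_dir" in meta:
            meta["fe_axis_dir"] = tuple(R @ np.asarray(meta["fe_axis_dir"]))
        return SurfaceMesh(m, self.label, meta)


@dataclass(frozen=True)
class ImplantParams:
    """Dimensions of the surrogate CR implant system (mm).

    The condyles are single-radius in the sagittal plane
    (``condyle_radius``) with a coronal rounding radius
    ``condyle_coronal_radius``; the insert dishes are near-conforming
    (dish radius >= condyle radius in both planes), emulating a
    deep-dished CR insert.
    """

    condyle_radius: float = 24.0
    condyle_spacing: float = 46.0
    condyle_width: float = 18.0
    condyle_coronal_radius: float = 12.0
    insert_dish_sagittal_radius: float = 24.5
    insert_dish_coronal_radius: float = 18.0
    # optional flat strip half-width at the dish bottom (0 = fully dished)
    insert_ap_flat: float = 0.0
    insert_thickness: float = 10.0
    insert_half_length: float = 20.5   # AP half-extent of insert block
    insert_half_width: float = 40.0    # ML half-extent of insert block
    insert_lip_height: float = 9.0     # dish wall height (deep-dished)
    eminence_height: float = 4.0       # intercondylar eminence cap
    tray_thickness: float = 10.0
    # internal twist of the native posterior condylar axis relative to the
    # epicondylar (flexion) axis; the reason the component is placed in
    # external rotation in the first place
    pca_twist_deg: float = 2.5
    # mesh resolution: the condyle facet sag must stay well below the
    # penalty penetration (~0.04 mm at physiologic loads) or the contact
    # response turns bumpy at the solver's working scale
    n_sagittal: int = 72
    n_coronal: int = 20
    insert_grid: float = 2.5
    # condylar arc in the sagittal plane, degrees from distal (0 = distal,
    # 90 = posterior); must reach past 90 so posterior-most points exist.
    sagittal_arc: tuple[float, float] = (-60.0, 145.0)

    def __post_init__(self):
        lengths = (
            self.condyle_radius, self.condyle_spacing, self.condyle_width,
            self.condyle_coronal_radius, self.insert_dish_sagittal_radius,
            self.insert_dish_coronal_radius, self.insert_thickness,
        )
        if any(v <= 0 for v in lengths):
            raise GeometryError("all implant dimensions must be positive")
        if self.insert_dish_sagittal_radius < self.condyle_radius:
            raise GeometryError(
                "sagittal dish radius must be >= condyle radius")
        if self.insert_dish_coronal_radius < self.condyle_coronal_radius:
            raise GeometryError(
                "coronal dish radius must be >= condyle coronal radius")
        if self.condyle_width / 2.0 > self.condyle_coronal_radius:
            raise GeometryError(
                "condyle width incompatible with coronal radius")


@dataclass(frozen=True)
class AlignmentCondition:
    """Femoral component placement relative to the femur's PCA.

    ``external_rotation_deg`` is the external rotation of the component's
    posterior condylar axis with respect to the femur's, about the femoral
    proximal-distal axis.
    """

    name: str
    external_rotation_deg: float


#: The three malrotation study conditions: the mechanically aligned target of
#: 3 degrees external, under- and over-rotated by 1.5 degrees.
CONDITIONS: dict[str, AlignmentCondition] = {
    "internal": AlignmentCondition("internal", 1.5),
    "baseline": AlignmentCondition("baseline", 3.0),
    "external": AlignmentCondition("external", 4.5),
}


@dataclass(frozen=True)
class WrapSphere:
    """Spherical wrapping surface fixed to a body (coords in body frame)."""

    label: str
    center: tuple[float, float, float]
    radius: float


def rotation_about(axis: np.ndarray, point: np.ndarray, angle_deg: float) -> np.ndarray:
    """4x4 rotation of ``angle_deg`` about ``axis`` through ``point``."""
    return trimesh.transformations.rotation_matrix(
        np.radians(angle_deg), axis, point)


# ---------------------------------------------------------------------------
# construction helpers
# ---------------------------------------------------------------------------

def _sagittal_dir(theta):
    """Unit direction in the x-y plane at sagittal angle theta (radians).

    theta = 0 points distally (-y), theta = pi/2 posteriorly (-x).
    """
    theta = np.asarray(theta)
    return np.stack([-np.sin(theta), -np.cos(theta), np.zeros_like(theta)], axis=-1)


def _close_and_orient(vertices: np.ndarray, faces: list) -> trimesh.Trimesh:
    mesh = trimesh.Trimesh(vertices=vertices, faces=np.asarray(faces),
                           process=True, validate=False)
    mesh.fix_normals()
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def _condyle_solid(R: float, rho: float, z_center: float, half_width: float,
                   arc_deg: tuple[float, float], n_sag: int, n_cor: int,
                   y_axis: float) -> trimesh.Trimesh:
    """Closed 'sausage' solid of one toroidal condyle.

    Articular surface: tube of radius ``rho`` swept along the circle of
    radius ``R - rho`` centred at (0, y_axis, z_center) in the sagittal
    plane, so the outermost fibre has sagittal radius exactly ``R``.
    Closed by a top flap through the tube centreline and end caps.
    """
    phi_max = np.arcsin(min(half_width / rho, 1.0))
    thetas = np.radians(np.linspace(arc_deg[0], arc_deg[1], n_sag + 1))
    phis = np.linspace(-phi_max, phi_max, n_cor + 1)

    d = _sagittal_dir(thetas)                      # (n_sag+1, 3)
    centerline = np.array([0.0, y_axis, z_center]) + (R - rho) * d
    # tube vertices: centerline + rho*(d*cos(phi) + z*sin(phi))
    zhat = np.array([0.0, 0.0, 1.0])
    pts = (centerline[:, None, :]
           + rho * (d[:, None, :] * np.cos(phis)[None, :, None]
                    + zhat * np.sin(phis)[None, :, None]))
    n_ring = n_cor + 1
    verts = pts.reshape(-1, 3)
    spine0 = len(verts)
    verts = np.vstack([verts, centerline])

    faces = []
    for i in range(n_sag):
        for j in range(n_cor):
            a = i * n_ring + j
            b = (i + 1) * n_ring + j
            faces.append([a, b, a + 1])
            faces.append([a + 1, b, b + 1])
    # top flaps connecting both phi edges to the spine
    for i in range(n_sag):
        e0a, e0b = i * n_ring, (i + 1) * n_ring
        e1a, e1b = i * n_ring + n_cor, (i + 1) * n_ring + n_cor
        s0, s1 = spine0 + i, spine0 + i + 1
        faces.append([e0a, s0, e0b])
        faces.append([e0b, s0, s1])
        faces.append([e1a, e1b, s1])
        faces.append([e1a, s1, s0])
    # end caps (fans to the spine endpoint)
    for j in range(n_cor):
        faces.append([j, j + 1, spine0])
        base = n_sag * n_ring
        faces.append([base + j + 1, base + j, spine0 + n_sag])
    return _close_and_orient(verts, faces)


def _make_femoral_component(p: ImplantParams) -> SurfaceMesh:
    halves = []
    for zc in (-p.condyle_spacing / 2.0, p.condyle_spacing / 2.0):
        halves.append(_condyle_solid(
            p.condyle_radius, p.condyle_coronal_radius, zc,
            p.condyle_width / 2.0, p.sagittal_arc,
            p.n_sagittal, p.n_coronal, y_axis=p.condyle_radius))
    mesh = trimesh.util.concatenate(halves)
    if not mesh.is_winding_consistent:
        raise GeometryError("femoral component mesh is not manifold")
    condyles = [
        {"center": (0.0, p.condyle_radius, zc),
         "axis": (0.0, 0.0, 1.0),        # torus plane normal
         "u1": (0.0, -1.0, 0.0),         # sagittal angle reference (distal)
         "u2": (-1.0, 0.0, 0.0),         # quadrature direction (posterior)
         "major_radius": p.condyle_radius - p.condyle_coronal_radius,
         "tube_radius": p.condyle_coronal_radius,
         "theta_range_deg": p.sagittal_arc,
         "phi_max_deg": float(np.degrees(np.arcsin(
             min(p.condyle_width / 2.0 / p.condyle_coronal_radius, 1.0))))}
        for zc in (-p.condyle_spacing / 2.0, p.condyle_spacing / 2.0)
    ]
    return SurfaceMesh(mesh, "femoral_component",
                       {"fe_axis_point": (0.0, p.condyle_radius, 0.0),
                        "fe_axis_dir": (0.0, 0.0, 1.0),
                        "condyles": condyles})


def _dish_height(p: ImplantParams, x: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Insert articular surface height y(x, z) (dish bottoms at y = 0)."""
    Rs, Rc = p.insert_dish_sagittal_radius, p.insert_dish_coronal_radius
    xs = np.minimum(np.maximum(np.abs(x) - p.insert_ap_flat, 0.0), Rs)
    ys = np.minimum(Rs - np.sqrt(np.maximum(Rs**2 - xs**2, 0.0)),
                    p.insert_lip_height)
    dz = np.minimum(np.abs(z - p.condyle_spacing / 2.0),
                    np.abs(z + p.condyle_spacing / 2.0))
    dz = np.minimum(dz, Rc)
    yc = np.minimum(Rc - np.sqrt(np.maximum(Rc**2 - dz**2, 0.0)),
                    p.eminence_height)
    return ys + yc


def _make_insert(p: ImplantParams) -> SurfaceMesh:
    nx = max(int(round(2 * p.insert_half_length / p.insert_grid)), 4)
    nz = max(int(round(2 * p.insert_half_width / p.insert_grid)), 4)
    x = np.linspace(-p.insert_half_length, p.insert_half_length, nx + 1)
    z = np.linspace(-p.insert_half_width, p.insert_half_width, nz + 1)
    X, Z = np.meshgrid(x, z, indexing="ij")
    Y = _dish_height(p, X, Z)
    top = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    bottom = np.stack([X, np.full_like(X, -p.insert_thickness), Z],
                      axis=-1).reshape(-1, 3)
    nvt = top.shape[0]
    verts = np.vstack([top, bottom])

    def vid(i, j, layer):
        return layer * nvt + i * (nz + 1) + j

    faces = []
    for i in range(nx):
        for j in range(nz):
            a, b, c, d = (vid(i, j, 0), vid(i + 1, j, 0),
                          vid(i + 1, j + 1, 0), vid(i, j + 1, 0))
            faces.append([a, b, c])
            faces.append([a, c, d])
            a, b, c, d = (vid(i, j, 1), vid(i + 1, j, 1),
                          vid(i + 1, j + 1, 1), vid(i, j + 1, 1))
            faces.append([a, c, b])
            faces.append([a, d, c])
    # side walls
    for i in range(nx):
        for (j, flip) in ((0, False), (nz, True)):
            a, b = vid(i, j, 0), vid(i + 1, j, 0)
            c, d = vid(i + 1, j, 1), vid(i, j, 1)
            quad = [[a, d, c], [a, c, b]] if not flip else [[a, c, d], [a, b, c]]
            faces.extend(quad)
    for j in range(nz):
        for (i, flip) in ((0, True), (nx, False)):
            a, b = vid(i, j, 0), vid(i, j + 1, 0)
            c, d = vid(i, j + 1, 1), vid(i, j, 1)
            quad = [[a, d, c], [a, c, b]] if not flip else [[a, c, d], [a, b, c]]
            faces.extend(quad)
    mesh = _close_and_orient(verts, faces)
    return SurfaceMesh(mesh, "insert",
                       {"grid": p.insert_grid,
                        "midline_z": 0.0,
                        "dish_centers_z": (-p.condyle_spacing / 2.0,
                                           p.condyle_spacing / 2.0)})


def _make_tray(p: ImplantParams) -> SurfaceMesh:
    box = trimesh.creation.box(
        extents=(2 * p.insert_half_length, p.tray_thickness,
                 2 * p.insert_half_width))
    box.apply_translation((0.0, -p.insert_thickness - p.tray_thickness / 2.0, 0.0))
    return SurfaceMesh(box, "tray", {})


def _make_femur_surrogate(p: ImplantParams) -> SurfaceMesh:
    """Bone surrogate: two condylar masses plus a shaft cylinder.

    The condylar masses are internally rotated by ``pca_twist_deg`` about
    the proximal axis, reproducing the native posterior condylar axis's
    internal twist relative to the epicondylar axis.
    """
    parts = []
    twist = rotation_about(np.array([0.0, 1.0, 0.0]),
                           np.array([0.0, p.condyle_radius, 0.0]),
                           p.pca_twist_deg)   # internal(+) for a right knee
    for zc in (-p.condyle_spacing / 2.0, p.condyle_spacing / 2.0):
        solid = _condyle_solid(
            p.condyle_radius + 1.0, p.condyle_coronal_radius + 1.0, zc,
            p.condyle_width / 2.0 + 1.0, p.sagittal_arc,
            p.n_sagittal, p.n_coronal, y_axis=p.condyle_radius)
        solid.apply_transform(twist)
        parts.append(solid)
    shaft = trimesh.creation.cylinder(radius=14.0, height=70.0, sections=24)
    shaft.apply_transform(rotation_about(np.array([1.0, 0, 0]),
                                         np.zeros(3), 90.0))
    shaft.apply_translation((0.0, p.condyle_radius + 40.0, 0.0))
    parts.append(shaft)
    return SurfaceMesh(trimesh.util.concatenate(parts), "femur", {})


#: Proximal-medial tibial bulge the sMCL wraps around (tibia frame, mm).
_TIBIA_WRAP = WrapSphere("tibia_wrap_medial", (0.0, -14.0, -24.0), 12.0)


def _make_tibia_surrogate(p: ImplantParams) -> tuple[SurfaceMesh, SurfaceMesh]:
    shaft = trimesh.creation.cylinder(radius=16.0, height=70.0, sections=24)
    shaft.apply_transform(rotation_about(np.array([1.0, 0, 0]),
                                         np.zeros(3), 90.0))
    y_top = -p.insert_thickness - p.tray_thickness
    shaft.apply_translation((0.0, y_top - 35.0, 0.0))
    tibia = SurfaceMesh(shaft, "tibia", {})

    sphere = trimesh.creation.icosphere(subdivisions=3,
                                        radius=_TIBIA_WRAP.radius)
    sphere.apply_translation(_TIBIA_WRAP.center)
    # keep the medial-facing portion of the bulge as the wrap patch
    centroid_z = sphere.triangles_center[:, 2]
    mask = centroid_z <= _TIBIA_WRAP.center[2] - 0.25 * _TIBIA_WRAP.radius
    patch = sphere.submesh([np.nonzero(mask)[0]], append=True)
    wrap = SurfaceMesh(patch, _TIBIA_WRAP.label,
                       {"center": _TIBIA_WRAP.center,
                        "radius": _TIBIA_WRAP.radius})
    return tibia, wrap


#: Default anatomical insertion sites for the seed bundles, per ligament,
#: ordered anterior -> posterior. Femoral points are in the femur frame,
#: tibial points in the tibia frame (both coincide with the world frame at
#: the reference pose). Derived from standard descriptions: sMCL from the
#: medial epicondyle to the broad insertion ~5.5 cm distal on the medial
#: tibia; LCL from the lateral epicondyle to the fibular head; PCL from the
#: medial wall of the intercondylar notch to the posterior intercondylar
#: fossa below the joint line.
DEFAULT_INSERTIONS: dict[str, dict[str, list[tuple[float, float, float]]]] = {
    # epicondylar origins sit on the flexion axis (x = 0, y = condylar
    # centre height) so the collaterals are near-isometric through flexion,
    # with the anterior fibers tightening slightly as the knee flexes
    # the sMCL runs to an antero-medial tibial footprint and the LCL to the
    # postero-lateral fibular head; the opposing obliquities make external
    # rotation the stiffer direction, as in the native knee
    # the sMCL origin sits slightly anterior of the flexion axis, so its
    # fibers recruit with flexion (the anterior-fiber tightening of the
    # native superficial MCL) and medial compression persists in flexion
    "sMCL": {
        "femur": [(3.0, 24.0, -36.0), (1.5, 24.0, -36.0), (0.0, 24.0, -36.0)],
        "tibia": [(12.0, -55.0, -29.0), (7.0, -55.0, -29.0), (2.0, -55.0, -29.0)],
    },
    "LCL": {
        "femur": [(1.5, 24.0, 36.0), (0.0, 24.0, 36.0), (-1.5, 24.0, 36.0)],
        "tibia": [(-8.0, -38.0, 33.0), (-12.0, -38.0, 33.0), (-16.0, -38.0, 33.0)],
    },
    # the PCL origin sits antero-distal to the flexion axis on the notch
    # wall, so the ligament lengthens ~40 % between extension and 90 deg of
    # flexion and engages under posterior drawer in deep flexion
    "PCL": {
        "femur": [(2.0, 13.0, -6.0), (-2.0, 14.0, -6.0)],
        "tibia": [(-28.0, -8.0, 0.0), (-32.0, -12.0, 0.0)],
    },
}


@dataclass
class KneeGeometry:
    """The full surrogate geometry set in the reference (extension) pose."""

    params: ImplantParams
    meshes: dict[str, SurfaceMesh]
    insertions: dict[str, dict[str, list[tuple[float, float, float]]]]
    wrap_spheres: list[WrapSphere]
    fe_axis_point: np.ndarray
    component_transform: np.ndarray  # placement of the femoral component
    condition: AlignmentCondition | None = None

    @property
    def component(self) -> SurfaceMesh:
        return self.meshes["femoral_component"]

    @property
    def insert(self) -> SurfaceMesh:
        return self.meshes["insert"]


def make_knee_geometry(params: ImplantParams | None = None) -> KneeGeometry:
    """Build the neutral (un-malrotated) surrogate right-knee geometry."""
    p = params or ImplantParams()
    component = _make_femoral_component(p)
    insert = _make_insert(p)
    tray = _make_tray(p)
    femur = _make_femur_surrogate(p)
    tibia, wrap = _make_tibia_surrogate(p)
    meshes = {m.label: m for m in (component, insert, tray, femur, tibia, wrap)}
    return KneeGeometry(
        params=p,
        meshes=meshes,
        insertions={k: {s: list(v2) for s, v2 in v.items()}
                    for k, v in DEFAULT_INSERTIONS.items()},
        wrap_spheres=[_TIBIA_WRAP],
        fe_axis_point=np.array([0.0, p.condyle_radius, 0.0]),
        component_transform=np.eye(4),
    )


# ---------------------------------------------------------------------------
# posterior condylar axis & component placement
# ---------------------------------------------------------------------------

def compute_pca(mesh: SurfaceMesh | trimesh.Trimesh,
                posterior_direction: np.ndarray = (-1.0, 0.0, 0.0)) -> np.ndarray:
    """Posterior condylar axis of a two-condyle mesh.

    Splits the mesh at the sagittal midplane of its bounding box and returns
    the posterior-most vertex of each half, ordered (medial, lateral) for the
    standard frame, as a (2, 3) array.
    """
    tm = mesh.mesh if isinstance(mesh, SurfaceMesh) else mesh
    v = np.asarray(tm.vertices)
    post = np.asarray(posterior_direction, dtype=float)
    n = np.linalg.norm(post)
    if n == 0:
        raise GeometryError("posterior direction must be non-zero")
    post = post / n
    # restrict to the posterior condylar region so shafts/flanges anterior to
    # the condyles do not mask the intercondylar gap
    proj = v @ post
    near = v[proj >= proj.max() - 0.2 * (proj.max() - proj.min())]
    z_mid = 0.5 * (near[:, 2].min() + near[:, 2].max())
    med, lat = near[near[:, 2] < z_mid], near[near[:, 2] >= z_mid]
    if len(med) == 0 or len(lat) == 0:
        raise GeometryError("mesh has no intercondylar split at the midplane")
    # require an actual gap between condylar halves near the midplane
    gap = lat[:, 2].min() - med[:, 2].max()
    if gap < 2.0:      # anatomical intercondylar gaps are >> 2 mm
        raise GeometryError("no intercondylar gap found; single condyle?")
    def refine(half):
        """Sub-facet posterior extremum: quadratic fit of the posterior
        projection against height around the best vertex, so the result is
        insensitive to the mesh refinement level."""
        proj = half @ post
        best = half[np.argmax(proj)]
        near = half[(proj >= proj.max() - 1.5)
                    & (np.abs(half[:, 2] - best[2]) <= 1.0)]
        if len(near) < 5:
            near = half[proj >= proj.max() - 1.5]
        if len(near) < 5:
            return best
        y = near[:, 1] - best[1]
        try:
            coef = np.polyfit(y, near @ post, 2)
        except np.linalg.LinAlgError:
            return best
        if coef[0] >= -1e-9:
            return best
        y_star = float(np.clip(-coef[1] / (2 * coef[0]), y.min(), y.max()))
        p_star = np.polyval(coef, y_star)
        out = best.copy()
        out[1] = best[1] + y_star
        out += (p_star - best @ post) * post
        return out

    return np.array([refine(med), refine(lat)])


def _axial_external_angle(femur_pca: np.ndarray, component_pca: np.ndarray) -> float:
    """Signed external rotation (deg) of the component PCA vs the femur PCA,
    projected onto the axial (x-z) plane. Positive = external for a right
    knee (medial end of the axis swung anteriorly)."""
    f = np.asarray(femur_pca[1], float) - np.asarray(femur_pca[0], float)
    c = np.asarray(component_pca[1], float) - np.asarray(component_pca[0], float)
    f[1] = 0.0
    c[1] = 0.0
    if np.linalg.norm(f) < 1e-12 or np.linalg.norm(c) < 1e-12:
        raise GeometryError("degenerate (zero-length) posterior condylar axis")
    # signed angle about +y from f to c; external rotation is negative about +y
    ang = np.degrees(np.arctan2(np.cross(f, c)[1], np.dot(f, c)))
    return -ang


def align_component(femur_pca: np.ndarray, component_pca: np.ndarray,
                    condition: AlignmentCondition) -> np.ndarray:
    """Rigid transform placing the component at the requested external
    rotation from the femoral PCA, about the proximal-distal axis through
    the femoral PCA midpoint (a pure axial-plane rotation)."""
    current = _axial_external_angle(femur_pca, component_pca)
    delta_external = condition.external_rotation_deg - current
    midpoint = 0.5 * (np.asarray(femur_pca[0], float)
                      + np.asarray(femur_pca[1], float))
    # external(+) = negative rotation about +y for a right knee
    return rotation_about(np.array([0.0, 1.0, 0.0]), midpoint, -delta_external)


def place_component(geom: KneeGeometry,
                    condition: AlignmentCondition | str) -> KneeGeometry:
    """Return a copy of ``geom`` with the femoral component malrotated.

    Bone, insert and tray meshes are shared (identical across conditions);
    only the component mesh and its placement transform differ.
    """
    if isinstance(condition, str):
        condition = CONDITIONS[condition]
    femur_pca = compute_pca(geom.meshes["femur"])
    comp_pca = compute_pca(geom.meshes["femoral_component"])
    T = align_component(femur_pca, comp_pca, condition)
    meshes = dict(geom.meshes)
    meshes["femoral_component"] = geom.meshes["femoral_component"].transformed(T)
    return replace(geom, meshes=meshes,
                   component_transform=T @ geom.component_transform,
                   condition=condition)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_geometry(geom: KneeGeometry, out_dir: str | Path,
                  file_type: str = "stl") -> list[Path]:
    """Write one STL (binary) or PLY (ascii) file per labelled part."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for label, sm in geom.meshes.items():
        path = out / f"{label}.{file_type}"
        if file_type == "ply":
            data = sm.mesh.export(file_type="ply", encoding="ascii")
        else:
            data = sm.mesh.export(file_type=file_type)
        path.write_bytes(data if isinstance(data, bytes) else data.encode())
        written.append(path)
    return written


def load_geometry(in_dir: str | Path) -> dict[str, SurfaceMesh]:
    """Load every STL/PLY in a directory as labelled surfaces."""
    meshes = {}
    for path in sorted(Path(in_dir).iterdir()):
        if path.suffix.lower() in (".stl", ".ply"):
            meshes[path.stem] = SurfaceMesh(trimesh.load(str(path)), path.stem)
    return meshes
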