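"""Component-on-insert contact by inferior-superior penetration testing.

Contact between the rigid femoral component and the UHMWPE insert is
evaluated the way the joint-motion-simulator software does: sample points on
the insert articular surface are tested for penetration of the component
along the tibia's inferior-superior (IS) axis. Penetration depths feed a
penalty law — per-point normal pressure = penalty stiffness x depth — and
per-point forces are decomposed into medial/lateral compartment compressive
loads about the insert midline.

The per-point force is the exact gradient of the quadratic penalty energy
with respect to the sample's world motion: magnitude k * A_proj * d along
the direction n / (n . IS), where n is the component surface normal at the
hit. The activation ramps in quadratically over the first 0.01 mm of depth
so the contact stiffness is continuous, which the equilibrium solver's
Newton iteration relies on.

Two interchangeable engines produce the penetration field:

* analytic — used when the component carries its condylar torus parameters
  (the synthetic single-radius component always does): the IS-ray/torus
  intersection is solved by vectorized bisection and surface normals come
  from the torus implicit, so depths and normals are smooth to machine
  precision;
* mesh — a vectorized Moller-Trumbore first-hit ray caster against the
  component triangulation, for arbitrary geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import SurfaceMesh

__all__ = [
    "ContactField",
    "ContactSummary",
    "ContactModel",
    "penetration_field",
    "contact_loads",
    "contact_energy",
]

DEFAULT_PENALTY_STIFFNESS = 100.0   # N / mm per mm^2 of projected area
DEFAULT_FRICTION = 0.04
#: activation regularization depth (mm): the per-point pressure ramps in
#: quadratically over this depth so the contact stiffness is continuous at
#: activation; negligible at physiologic penetrations (~0.05 mm).
REG_DEPTH = 0.01
#: cap on the wall-slope magnification 1/|n . IS| of the penalty force
_MIN_IS_COMPONENT = 0.15


def _effective_depth(d: np.ndarray, d0: float = REG_DEPTH) -> np.ndarray:
    """C1 activation ramp: d^2/(2 d0) below d0, d - d0/2 above."""
    return np.where(d < d0, d * d / (2.0 * d0), d - 0.5 * d0)


class ContactError(ValueError):
    pass


@dataclass
class ContactField:
    """Per-sample penetration state on the insert articular surface."""

    points: np.ndarray        # (n,3) sample points, world (tibia side)
    depths: np.ndarray        # (n,) mm, >= 0
    areas: np.ndarray         # (n,) projected tributary areas, mm^2
    normals: np.ndarray       # (n,3) force directions on the tibia
                              # (unit IS component, pointing inferiorly)
    compartment: np.ndarray   # (n,) -1 medial, +1 lateral
    is_axis: np.ndarray       # world IS direction (tibial long axis)
    femur_points: np.ndarray | None = None   # (n,3) hits on the component

    def active(self) -> np.ndarray:
        return self.depths > 0.0


@dataclass
class ContactSummary:
    net_force: np.ndarray       # on the tibia, N
    net_moment: np.ndarray      # on the tibia about the moment centre, N*mm
    medial_force: float         # compressive (positive), N
    lateral_force: float        # compressive (positive), N
    max_penetration: float      # mm
    femur_moment: np.ndarray | None = None   # on the femur about the centre
    tangential_force: np.ndarray | None = None

    @property
    def net_compression(self) -> float:
        return self.medial_force + self.lateral_force


# ---------------------------------------------------------------------------
# mesh-ray engine
# ---------------------------------------------------------------------------

def _first_hit(origins: np.ndarray, direction: np.ndarray,
               v0: np.ndarray, e1: np.ndarray, e2: np.ndarray):
    """Vectorized Moller-Trumbore: nearest positive-t hit per ray.

    All rays share one direction, so the barycentric terms are affine in
    the origin and reduce to three matrix products. Returns (t, tri_index)
    with t = inf and index = -1 for misses.
    """
    d = direction
    pvec = np.cross(d[None, :], e2)              # (m,3)
    det = np.einsum("ij,ij->i", e1, pvec)        # (m,)
    ok = np.abs(det) > 1e-12
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    cd = np.cross(e1, d[None, :])                # (m,3)
    nt = np.cross(e1, e2)                        # (m,3)
    u = (origins @ pvec.T - np.einsum("ij,ij->i", v0, pvec)) * inv_det
    v = (origins @ cd.T - np.einsum("ij,ij->i", v0, cd)) * inv_det
    t = (origins @ nt.T - np.einsum("ij,ij->i", v0, nt)) * inv_det
    hit = (ok[None, :] & (u >= -1e-9) & (v >= -1e-9)
           & (u + v <= 1.0 + 1e-9) & (t > 1e-9))
    t = np.where(hit, t, np.inf)
    idx = np.argmin(t, axis=1)
    rows = np.arange(len(origins))
    tmin = t[rows, idx]
    idx = np.where(np.isfinite(tmin), idx, -1)
    return tmin, idx


# ---------------------------------------------------------------------------
# contact model
# ---------------------------------------------------------------------------

class ContactModel:
    """Precomputed contact pairing of one component and one insert mesh.

    Insert samples are the barycentres of upward-facing insert triangles
    (fixed in the tibia frame). ``component_pose`` passed to :meth:`field`
    is the world pose of the frame the component geometry is expressed in
    (for a placed component, simply the femur pose).
    """

    def __init__(self, component: SurfaceMesh, insert: SurfaceMesh,
                 midline_z: float | None = None):
        tm = insert.mesh
        fn = np.asarray(tm.face_normals)
        tops = fn[:, 1] > 0.5
        if not np.any(tops):
            raise ContactError("insert mesh has no upward articular surface")
        tri = np.asarray(tm.triangles[tops])
        self.samples_local = tri.mean(axis=1)                  # (n,3)
        areas = np.asarray(tm.area_faces)[tops]
        self.areas = areas * fn[tops, 1]                       # projected
        if midline_z is None:
            midline_z = float(insert.metadata.get("midline_z", 0.0))
        self.compartment = np.where(
            self.samples_local[:, 2] < midline_z, -1, 1)

        self._condyles = component.metadata.get("condyles")
        if not self._condyles:
            cm = component.mesh
            ctri = np.asarray(cm.triangles)
            self._v0 = ctri[:, 0]
            self._e1 = ctri[:, 1] - ctri[:, 0]
            self._e2 = ctri[:, 2] - ctri[:, 0]
            self._fnorm = np.asarray(cm.face_normals)

    # -- analytic torus engine ----------------------------------------
    def _field_analytic(self, component_pose, pts_world, is_axis):
        Rc, tc = component_pose[:3, :3], component_pose[:3, 3]
        n_pts = len(pts_world)
        depths = np.zeros(n_pts)
        normals = np.tile(-is_axis, (n_pts, 1))
        hits = pts_world.copy()
        u = -is_axis                                  # shared ray direction
        for c in self._condyles:
            ctr = Rc @ np.asarray(c["center"]) + tc
            a = Rc @ np.asarray(c["axis"])
            u1 = Rc @ np.asarray(c["u1"])
            u2 = Rc @ np.asarray(c["u2"])
            Rm, rho = c["major_radius"], c["tube_radius"]
            th0, th1 = np.radians(c["theta_range_deg"])
            phi_max = np.radians(c["phi_max_deg"])

            w0 = pts_world - ctr
            ax0 = w0 @ a
            w0p = w0 - ax0[:, None] * a
            A0 = np.einsum("ij,ij->i", w0p, w0p)
            F0 = (np.sqrt(A0) - Rm) ** 2 + ax0**2 - rho**2
            cand = F0 < 0.0
            if not np.any(cand):
                continue
            idx = np.nonzero(cand)[0]
            ua = float(u @ a)
            up = u - ua * a
            B0 = w0p[idx] @ up
            C0 = float(up @ up)
            ax_c = ax0[idx]
            A_c = A0[idx]

            def f_of(t):
                rin = np.sqrt(np.maximum(A_c + 2.0 * B0 * t + C0 * t * t,
                                         0.0))
                axt = ax_c + ua * t
                return (rin - Rm) ** 2 + axt**2 - rho**2

            lo = np.zeros(len(idx))
            hi = np.full(len(idx), 0.25)
            for _ in range(7):                       # up to 32 mm
                neg = f_of(hi) < 0.0
                if not np.any(neg):
                    break
                lo = np.where(neg, hi, lo)
                hi = np.where(neg, hi * 2.0, hi)
            for _ in range(50):
                mid = 0.5 * (lo + hi)
                neg = f_of(mid) < 0.0
                lo = np.where(neg, mid, lo)
                hi = np.where(neg, hi, mid)
            t = 0.5 * (lo + hi)

            wh = w0[idx] + t[:, None] * u
            axh = wh @ a
            whp = wh - axh[:, None] * a
            rinh = np.linalg.norm(whp, axis=1)
            theta = np.arctan2(whp @ u2, whp @ u1)
            phi = np.arctan2(axh, rinh - Rm)
            valid = ((theta >= th0) & (theta <= th1)
                     & (np.abs(phi) <= phi_max) & (t > 1e-12))
            if not np.any(valid):
                continue
            grad = 2.0 * ((1.0 - Rm / np.maximum(rinh, 1e-9))[:, None] * whp
                          + axh[:, None] * a)
            n = grad / np.linalg.norm(grad, axis=1, keepdims=True)
            comp = n @ is_axis                        # negative at contact
            valid &= comp < 0.0
            scale = 1.0 / np.maximum(np.abs(comp), _MIN_IS_COMPONENT)
            n_eff = n * scale[:, None]
            sel = idx[valid]
            depths[sel] = t[valid]
            normals[sel] = n_eff[valid]
            hits[sel] = pts_world[sel] - t[valid, None] * is_axis
        return depths, normals, hits

    # -- mesh-ray engine ----------------------------------------------
    def _field_mesh(self, component_pose, pts_world, is_axis):
        Rc, tc = component_pose[:3, :3], component_pose[:3, 3]
        origins = (pts_world - tc) @ Rc
        direction = -(Rc.T @ is_axis)
        n_pts = len(origins)
        depths = np.zeros(n_pts)
        normals = np.tile(-is_axis, (n_pts, 1))
        lo = self._v0.min(axis=0)
        hi = self._v0.max(axis=0)
        pad = 2.0
        cand = np.all((origins[:, [0, 2]] >= lo[[0, 2]] - pad)
                      & (origins[:, [0, 2]] <= hi[[0, 2]] + pad), axis=1)
        if np.any(cand):
            t, idx = _first_hit(origins[cand], direction,
                                self._v0, self._e1, self._e2)
            n_world = self._fnorm[np.where(idx >= 0, idx, 0)] @ Rc.T
            comp = n_world @ is_axis
            # a first hit on a downward-facing component triangle means the
            # sample sits inside the component solid
            inside = (idx >= 0) & (comp < 0.0)
            scale = 1.0 / np.maximum(np.abs(comp), _MIN_IS_COMPONENT)
            n_eff = np.where(inside[:, None], n_world * scale[:, None],
                             np.tile(-is_axis, (inside.size, 1)))
            depths[cand] = np.where(inside, t, 0.0)
            normals[cand] = n_eff
        hits = pts_world - depths[:, None] * is_axis
        return depths, normals, hits

    def field(self, component_pose: np.ndarray,
              tibia_pose: np.ndarray) -> ContactField:
        """Penetration field for the posed bodies (world frame output)."""
        Rt, tt = tibia_pose[:3, :3], tibia_pose[:3, 3]
        pts_world = self.samples_local @ Rt.T + tt
        is_axis = Rt[:, 1]                       # tibial long axis, world
        if self._condyles:
            depths, normals, hits = self._field_analytic(
                component_pose, pts_world, is_axis)
        else:
            depths, normals, hits = self._field_mesh(
                component_pose, pts_world, is_axis)
        return ContactField(pts_world, depths, self.areas, normals,
                            self.compartment, is_axis, hits)


def penetration_field(component: SurfaceMesh, insert: SurfaceMesh,
                      femur_pose: np.ndarray, tibia_pose: np.ndarray,
                      engine: str = "auto") -> ContactField:
    """One-shot penetration field (see ContactModel for the cached form).

    ``engine`` may be "auto" (analytic when torus metadata is present),
    "mesh" or "analytic".
    """
    model = ContactModel(component, insert)
    if engine == "mesh":
        cm = component.mesh
        ctri = np.asarray(cm.triangles)
        model._condyles = None
        model._v0 = ctri[:, 0]
        model._e1 = ctri[:, 1] - ctri[:, 0]
        model._e2 = ctri[:, 2] - ctri[:, 0]
        model._fnorm = np.asarray(cm.face_normals)
    elif engine == "analytic" and not model._condyles:
        raise ContactError("component carries no analytic condyle data")
    return model.field(femur_pose, tibia_pose)


def contact_loads(field: ContactField,
                  penalty_stiffness: float = DEFAULT_PENALTY_STIFFNESS,
                  friction_coefficient: float = 0.0,
                  sliding_direction: np.ndarray | None = None,
                  moment_center: np.ndarray | None = None) -> ContactSummary:
    """Penalty forces and compartment decomposition for a field.

    Normal pressure is ``penalty_stiffness x depth`` (with the C1
    activation ramp); the per-point force acts along the local contact
    normal over the tributary area. With a positive friction coefficient
    and a sliding direction, a Coulomb tangential term mu * |N| opposing
    the sliding is added (zero at true static equilibrium, where no
    sliding occurs).
    """
    if penalty_stiffness < 0:
        raise ContactError("penalty stiffness must be non-negative")
    if moment_center is None:
        moment_center = np.zeros(3)
    mag = penalty_stiffness * _effective_depth(field.depths) * field.areas
    forces = mag[:, None] * field.normals                          # on tibia
    is_comp = forces @ field.is_axis                               # <= 0
    medial = -float(is_comp[field.compartment < 0].sum())
    lateral = -float(is_comp[field.compartment > 0].sum())
    net = forces.sum(axis=0)
    moments = np.cross(field.points - moment_center, forces).sum(axis=0)
    fem_pts = field.femur_points if field.femur_points is not None \
        else field.points
    fem_moment = np.cross(fem_pts - moment_center, -forces).sum(axis=0)
    tangential = None
    if friction_coefficient > 0 and sliding_direction is not None:
        s = np.asarray(sliding_direction, dtype=float)
        n = np.linalg.norm(s)
        if n > 0:
            tangential = -friction_coefficient * mag.sum() * (s / n)
            net = net + tangential
            # applied at the pressure centroid of the contact patch
            if mag.sum() > 0:
                centroid = (field.points * mag[:, None]).sum(axis=0) / mag.sum()
                moments = moments + np.cross(centroid - moment_center,
                                             tangential)
    return ContactSummary(
        net_force=net,
        net_moment=moments,
        medial_force=medial,
        lateral_force=lateral,
        max_penetration=float(field.depths.max(initial=0.0)),
        femur_moment=fem_moment,
        tangential_force=tangential,
    )


def contact_energy(field: ContactField,
                   penalty_stiffness: float = DEFAULT_PENALTY_STIFFNESS) -> float:
    """Elastic penalty energy (N*mm) stored in the contact field.

    Integral of the regularized per-point force over penetration depth.
    """
    d = field.depths
    d0 = REG_DEPTH
    e = np.where(d < d0, d**3 / (6.0 * d0),
                 0.5 * (d - 0.5 * d0) ** 2 + d0**2 / 24.0)
    return float(penalty_stiffness * np.sum(field.areas * e))
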