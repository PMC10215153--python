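"""Multifiber virtual ligament system.

Each ligament is a fan of point-to-point nonlinear fibers ("bundles").
A bundle carries a stiffness k (N per unit strain), a reference strain
eps_r (% , the strain at the full-extension reference pose) and a zero-force
(slack) length l_0. The force law is the standard quadratic-toe / linear
law used in knee ligament modelling (Blankevoort-type):

    f(eps) = 0                        eps <= 0
           = k * eps^2 / (4 eps_t)    0 < eps <= 2 eps_t
           = k * (eps - eps_t)        eps > 2 eps_t

with toe transition strain eps_t = 0.03. Reference strains tie the model to
measured ligament recruitment: l_0 is back-computed from the bundle length
measured on the geometry at the reference pose via

    eps_r = (l_r - l_0) / l_0 * 100 %

so the strain field at extension is preserved on any surrogate geometry.

Superficial MCL bundles wrap around the proximal-medial tibial bulge: if the
straight fiber penetrates the wrap sphere, the fiber is bent at a single via
point pushed out beyond the surface — the intersection of the two in-plane
tangent lines, which is the shortest single-bend path with zero residual
penetration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

from .geometry import KneeGeometry, WrapSphere

__all__ = [
    "LigamentBundle",
    "LigamentSet",
    "FiberForceLaw",
    "WrapResult",
    "reference_strain",
    "slack_length",
    "fiber_tension",
    "fiber_energy",
    "augment_bundles",
    "calibrate_stiffness",
    "wrap_path",
    "ligament_loads",
    "load_parameter_table",
    "build_ligament_set",
]

DEFAULT_TOE_STRAIN = 0.03


class LigamentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Eq.-style strain bookkeeping
# ---------------------------------------------------------------------------

def reference_strain(l_r: float, l_0: float) -> float:
    """Reference strain (%) from reference length and zero-force length."""
    if l_0 <= 0:
        raise LigamentError("zero-force length must be positive")
    return (l_r - l_0) / l_0 * 100.0


def slack_length(l_r: float, eps_r_pct: float) -> float:
    """Zero-force length from reference length and reference strain (%)."""
    if eps_r_pct <= -100.0:
        raise LigamentError("reference strain must exceed -100 %")
    return l_r / (1.0 + eps_r_pct / 100.0)


@dataclass(frozen=True)
class FiberForceLaw:
    """Quadratic-toe / linear fiber force law."""

    toe_strain: float = DEFAULT_TOE_STRAIN

    def tension(self, strain, k):
        return fiber_tension(strain, k, self.toe_strain)

    def energy(self, strain, k, l_0):
        return fiber_energy(strain, k, l_0, self.toe_strain)


def fiber_tension(strain, k, toe_strain: float = DEFAULT_TOE_STRAIN):
    """Fiber tension (N) at the given engineering strain."""
    eps = np.asarray(strain, dtype=float)
    t = toe_strain
    toe = k * eps**2 / (4.0 * t)
    lin = k * (eps - t)
    out = np.where(eps <= 0.0, 0.0, np.where(eps <= 2.0 * t, toe, lin))
    return float(out) if np.isscalar(strain) else out


def fiber_energy(strain, k, l_0, toe_strain: float = DEFAULT_TOE_STRAIN):
    """Elastic energy (N*mm) stored in a fiber of slack length l_0 (mm).

    Integral of tension over elongation: dE = f(eps) * l_0 * deps.
    """
    eps = np.asarray(strain, dtype=float)
    t = toe_strain
    toe = k * eps**3 / (12.0 * t)
    e_2t = k * (2.0 * t) ** 3 / (12.0 * t)          # energy at eps = 2t
    lin = e_2t + 0.5 * k * ((eps - t) ** 2 - t**2)
    out = l_0 * np.where(eps <= 0.0, 0.0, np.where(eps <= 2.0 * t, toe, lin))
    return float(out) if np.isscalar(strain) else out


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------

@dataclass
class LigamentBundle:
    """One point-to-point fiber of a multifiber ligament."""

    name: str                      # e.g. "m-sMCL"
    ligament: str                  # "sMCL" | "LCL" | "PCL"
    femur_point: np.ndarray        # femur frame, mm
    tibia_point: np.ndarray        # tibia frame, mm
    stiffness: float               # N per unit strain
    ref_strain_pct: float          # % at the reference pose
    slack_length_mm: float = float("nan")
    ref_length_mm: float = float("nan")
    wrap_surfaces: tuple[str, ...] = ()

    def __post_init__(self):
        self.femur_point = np.asarray(self.femur_point, dtype=float)
        self.tibia_point = np.asarray(self.tibia_point, dtype=float)
        if self.stiffness <= 0:
            raise LigamentError(f"{self.name}: stiffness must be positive")
        if not math.isnan(self.slack_length_mm):
            if self.slack_length_mm <= 0 or self.ref_length_mm <= 0:
                raise LigamentError(f"{self.name}: lengths must be positive")
            implied = reference_strain(self.ref_length_mm, self.slack_length_mm)
            if abs(implied - self.ref_strain_pct) > 1e-9 * max(
                    1.0, abs(self.ref_strain_pct)):
                raise LigamentError(
                    f"{self.name}: reference strain inconsistent with lengths")


@dataclass
class LigamentSet:
    """Ordered bundles per ligament (anterior -> posterior)."""

    ligaments: dict[str, list[LigamentBundle]]
    force_law: FiberForceLaw = field(default_factory=FiberForceLaw)
    wrap_spheres: list[WrapSphere] = field(default_factory=list)

    def bundles(self) -> list[LigamentBundle]:
        return [b for lig in self.ligaments.values() for b in lig]

    def validate_final_model(self) -> None:
        counts = {k: len(v) for k, v in self.ligaments.items()}
        expected = {"sMCL": 5, "LCL": 5, "PCL": 3}
        if counts != expected:
            raise LigamentError(f"final model must have {expected}, got {counts}")
        for b in self.ligaments["sMCL"]:
            if not b.wrap_surfaces:
                raise LigamentError(f"{b.name}: sMCL bundles must wrap the tibia")


# ---------------------------------------------------------------------------
# augmentation & calibration
# ---------------------------------------------------------------------------

_PREFIX_BETWEEN = {("a", "m"): "am", ("m", "p"): "mp", ("a", "p"): "m"}


def _bundle_prefix(name: str) -> tuple[str, str]:
    """Split 'am-sMCL' -> ('am', '-sMCL'), 'amLCL' -> ('am', 'LCL')."""
    for lig in ("sMCL", "LCL", "PCL"):
        for sep in ("-", ""):
            suffix = sep + lig
            if name.endswith(suffix):
                return name[: len(name) - len(suffix)], suffix
    return name, ""


def _midname(n1: str, n2: str) -> str:
    p1, s1 = _bundle_prefix(n1)
    p2, s2 = _bundle_prefix(n2)
    if s1 == s2 and (p1, p2) in _PREFIX_BETWEEN:
        return _PREFIX_BETWEEN[(p1, p2)] + s1
    return f"{n1}+{n2}"


def augment_bundles(bundles: list[LigamentBundle]) -> list[LigamentBundle]:
    """Insert one interpolated bundle between every adjacent pair.

    New insertions are the midpoints of the neighbours' insertions; the new
    reference strain is the arithmetic mean of the neighbours'; the nominal
    new stiffness is likewise the mean (subject to later calibration).
    Collaterals go 3 -> 5 bundles, the PCL 2 -> 3.
    """
    if len(bundles) < 2:
        raise LigamentError("augmentation needs at least two bundles")
    out: list[LigamentBundle] = []
    for left, right in zip(bundles[:-1], bundles[1:]):
        new = LigamentBundle(
            name=_midname(left.name, right.name),
            ligament=left.ligament,
            femur_point=0.5 * (left.femur_point + right.femur_point),
            tibia_point=0.5 * (left.tibia_point + right.tibia_point),
            stiffness=0.5 * (left.stiffness + right.stiffness),
            ref_strain_pct=0.5 * (left.ref_strain_pct + right.ref_strain_pct),
            wrap_surfaces=left.wrap_surfaces,
        )
        out.extend([left, new])
    out.append(bundles[-1])
    return out


def _bundle_length(bundle: LigamentBundle, femur_pose: np.ndarray,
                   tibia_pose: np.ndarray,
                   wrap_spheres: list[WrapSphere] | None = None) -> float:
    res = wrap_path(bundle, wrap_spheres or [], femur_pose, tibia_pose)
    return res.length


def calibrate_stiffness(original: list[LigamentBundle],
                        augmented: list[LigamentBundle],
                        distraction_pose: tuple[np.ndarray, np.ndarray],
                        wrap_spheres: list[WrapSphere] | None = None,
                        law: FiberForceLaw | None = None) -> list[LigamentBundle]:
    """Rescale augmented-bundle stiffnesses to conserve ligament force.

    At the distracted pose (which must engage every bundle in both lists)
    the augmented ligament's total fiber tension is matched to the original
    representation's total by one uniform per-ligament factor. Uniform
    scaling also preserves the relative anterior/posterior force
    distribution of the pre-existing bundles exactly.
    """
    law = law or FiberForceLaw()
    femur_pose, tibia_pose = distraction_pose

    def total(bundles):
        tot = 0.0
        for b in bundles:
            L = _bundle_length(b, femur_pose, tibia_pose, wrap_spheres)
            if math.isnan(b.slack_length_mm):
                raise LigamentError(f"{b.name}: slack length not set")
            eps = (L - b.slack_length_mm) / b.slack_length_mm
            if eps <= 0:
                raise LigamentError(
                    f"{b.name} is slack at the distraction pose; "
                    "distraction insufficient for calibration")
            tot += law.tension(eps, b.stiffness)
        return tot

    t_orig = total(original)
    t_aug = total(augmented)
    factor = t_orig / t_aug
    return [replace(b, stiffness=b.stiffness * factor) for b in augmented]


# ---------------------------------------------------------------------------
# wrapping
# ---------------------------------------------------------------------------

@dataclass
class WrapResult:
    points: np.ndarray      # (2,3) straight or (3,3) with via point, world
    length: float
    wrapped: bool
    surface: str | None = None


def _segment_sphere_depth(a: np.ndarray, b: np.ndarray,
                          c: np.ndarray, r: float) -> float:
    """Penetration depth of segment a-b into sphere (c, r); <=0 if clear."""
    d = b - a
    L2 = float(d @ d)
    t = float(np.clip(((c - a) @ d) / L2, 0.0, 1.0)) if L2 > 0 else 0.0
    closest = a + t * d
    return r - float(np.linalg.norm(closest - c))


def _sphere_via_point(a: np.ndarray, b: np.ndarray,
                      c: np.ndarray, r: float) -> np.ndarray:
    """Single bend point clearing the sphere: intersection of the two
    in-plane tangent lines from the endpoints, on the shallow side."""
    u = a - c
    w = b - c
    nrm = np.cross(u, w)
    n_len = np.linalg.norm(nrm)
    if n_len < 1e-12:
        # endpoints collinear with the centre: bend in any perpendicular
        # plane; pick a deterministic one
        seed = np.array([0.0, 0.0, 1.0])
        if abs(u @ seed) > 0.99 * np.linalg.norm(u):
            seed = np.array([0.0, 1.0, 0.0])
        nrm = np.cross(u, seed)
        n_len = np.linalg.norm(nrm)
    nrm = nrm / n_len
    e1 = u / np.linalg.norm(u)
    e2 = np.cross(nrm, e1)
    # in-plane coordinates (circle of radius r at the origin)
    A = np.array([float(u @ e1), 0.0])
    B = np.array([float(w @ e1), float(w @ e2)])
    if B[1] < 0:  # enforce B on the positive-angle side
        e2 = -e2
        B[1] = -B[1]
    ra, rb = np.linalg.norm(A), np.linalg.norm(B)
    gamma = math.atan2(B[1], B[0])
    ta = math.acos(min(r / ra, 1.0))            # tangent angle from A side
    tb = gamma - math.acos(min(r / rb, 1.0))    # tangent angle from B side
    pa = r * np.array([math.cos(ta), math.sin(ta)])
    pb = r * np.array([math.cos(tb), math.sin(tb)])

    def intersect(p0, d0, p1, d1):
        M = np.array([d0, -d1]).T
        rhs = p1 - p0
        det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
        if abs(det) < 1e-12:
            return 0.5 * (pa + pb)
        s = (rhs[0] * M[1, 1] - rhs[1] * M[0, 1]) / det
        return p0 + s * d0

    v2 = intersect(A, pa - A, B, pb - B)
    return c + v2[0] * e1 + v2[1] * e2


def wrap_path(bundle: LigamentBundle, wrap_spheres: list[WrapSphere],
              femur_pose: np.ndarray, tibia_pose: np.ndarray) -> WrapResult:
    """Fiber path and effective length for the posed bodies.

    The straight femur->tibia segment is used unless it penetrates one of
    the bundle's wrap surfaces, in which case the fiber is bent at the
    minimal single via point that clears the surface. The effective length
    is the summed sub-segment length (always >= the chord length).
    """
    a = (femur_pose[:3, :3] @ bundle.femur_point) + femur_pose[:3, 3]
    b = (tibia_pose[:3, :3] @ bundle.tibia_point) + tibia_pose[:3, 3]
    best: WrapResult | None = None
    for ws in wrap_spheres:
        if ws.label not in bundle.wrap_surfaces:
            continue
        c = (tibia_pose[:3, :3] @ np.asarray(ws.center)) + tibia_pose[:3, 3]
        if (np.linalg.norm(a - c) < ws.radius
                or np.linalg.norm(b - c) < ws.radius):
            raise LigamentError(
                f"{bundle.name}: insertion lies inside wrap surface {ws.label}")
        depth = _segment_sphere_depth(a, b, c, ws.radius)
        if depth <= 0:
            continue
        v = _sphere_via_point(a, b, c, ws.radius)
        length = float(np.linalg.norm(v - a) + np.linalg.norm(b - v))
        res = WrapResult(np.array([a, v, b]), length, True, ws.label)
        if best is None or res.length > best.length:
            best = res   # deepest wrap wins if several surfaces intersect
    if best is not None:
        return best
    return WrapResult(np.array([a, b]), float(np.linalg.norm(b - a)), False)


# ---------------------------------------------------------------------------
# loads
# ---------------------------------------------------------------------------

def ligament_loads(lig_set: LigamentSet, femur_pose: np.ndarray,
                   tibia_pose: np.ndarray,
                   moment_center: np.ndarray | None = None):
    """Resolve fiber tensions to joint loads on the tibia.

    Each fiber pulls its femoral insertion A toward the first path point
    with tension T; by two-body statics of the massless fiber (including a
    possible bend reaction on a tibia-fixed wrap surface) the total load on
    the tibia is exactly minus the load on the femur:

        F_tibia = -T * unit(next - A),   M_tibia = (A - center) x F_tibia.

    Returns ``(net_force, net_moment, per_bundle)`` where ``per_bundle``
    maps bundle name to a dict with the tension, strain, world application
    point (femoral insertion) and force-on-tibia vector.
    """
    if moment_center is None:
        moment_center = np.zeros(3)
    law = lig_set.force_law
    net_f = np.zeros(3)
    net_m = np.zeros(3)
    per = {}
    for b in lig_set.bundles():
        res = wrap_path(b, lig_set.wrap_spheres, femur_pose, tibia_pose)
        L = res.length
        eps = (L - b.slack_length_mm) / b.slack_length_mm
        T = law.tension(max(eps, 0.0), b.stiffness) if eps > 0 else 0.0
        a = res.points[0]
        nxt = res.points[1]
        seg = nxt - a
        seg_len = np.linalg.norm(seg)
        u = seg / seg_len if seg_len > 0 else np.zeros(3)
        f_tib = -T * u
        net_f += f_tib
        net_m += np.cross(a - moment_center, f_tib)
        per[b.name] = {
            "tension": float(T),
            "strain": float(eps),
            "length": float(L),
            "point": a,
            "force_on_tibia": f_tib,
            "wrapped": res.wrapped,
        }
    return net_f, net_m, per


def total_ligament_energy(lig_set: LigamentSet, femur_pose: np.ndarray,
                          tibia_pose: np.ndarray) -> float:
    """Total elastic energy (N*mm) stored in all fibers."""
    law = lig_set.force_law
    total = 0.0
    for b in lig_set.bundles():
        L = wrap_path(b, lig_set.wrap_spheres, femur_pose, tibia_pose).length
        eps = (L - b.slack_length_mm) / b.slack_length_mm
        if eps > 0:
            total += law.energy(eps, b.stiffness, b.slack_length_mm)
    return total


# ---------------------------------------------------------------------------
# parameter table & model assembly
# ---------------------------------------------------------------------------

def load_parameter_table(path=None) -> dict:
    """Load the packaged ligament parameter table (stiffness N per unit
    strain, reference strain %) or a user-provided YAML of the same shape."""
    if path is None:
        src = resources.files("vjms.data").joinpath("ligaments_tka.yaml")
        text = src.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


def _measure_reference_lengths(bundles: list[LigamentBundle],
                               wrap_spheres: list[WrapSphere]):
    eye = np.eye(4)
    out = []
    for b in bundles:
        l_r = _bundle_length(b, eye, eye, wrap_spheres)
        l_0 = slack_length(l_r, b.ref_strain_pct)
        out.append(replace(b, ref_length_mm=l_r, slack_length_mm=l_0))
    return out


def _distraction_pose(bundles: list[LigamentBundle],
                      wrap_spheres: list[WrapSphere],
                      margin: float = 1.25):
    """Pure inferior tibial translation engaging every bundle.

    The magnitude is ``margin`` times the smallest translation at which the
    slackest bundle reaches its zero-force length (bisection, deterministic).
    """
    eye = np.eye(4)

    def min_strain(dist):
        pose = np.eye(4)
        pose[1, 3] = -dist
        worst = np.inf
        for b in bundles:
            L = _bundle_length(b, eye, pose, wrap_spheres)
            worst = min(worst, (L - b.slack_length_mm) / b.slack_length_mm)
        return worst

    lo, hi = 0.0, 5.0
    while min_strain(hi) <= 0.0:
        hi *= 2.0
        if hi > 500.0:
            raise LigamentError("could not find an engaging distraction")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if min_strain(mid) <= 0.0:
            lo = mid
        else:
            hi = mid
    dist = margin * hi
    pose = np.eye(4)
    pose[1, 3] = -dist
    return (np.eye(4), pose), dist


def build_ligament_set(geom: KneeGeometry, table: dict | None = None,
                       law: FiberForceLaw | None = None,
                       calibrate: bool = True) -> LigamentSet:
    """Assemble the final 13-bundle model on the given geometry.

    Collateral ligaments use the five printed parameter sets directly (the
    table already contains the interpolated am/mp bundles); their am/mp
    insertions are the midpoints of the neighbouring seed insertions, per
    the augmentation rule. The PCL table prints only the anterior and
    posterior bundles: the middle bundle is created by augmentation and the
    PCL stiffnesses rescaled so total PCL tension at a fully engaging
    distracted pose is conserved.
    """
    table = table or load_parameter_table()
    law = law or FiberForceLaw(table.get("toe_strain", DEFAULT_TOE_STRAIN))
    wrap_spheres = list(geom.wrap_spheres)
    params = {e["name"]: e for e in table["bundles"]}

    ligaments: dict[str, list[LigamentBundle]] = {}
    pcl_seed: list[LigamentBundle] = []
    for lig, ins in geom.insertions.items():
        wrap = tuple(table.get("wrap", {}).get(lig, ()))
        seeds = []
        prefixes = ["a", "m", "p"] if len(ins["femur"]) == 3 else ["a", "p"]
        sep = "-" if lig == "sMCL" else ""
        for pref, fp, tp in zip(prefixes, ins["femur"], ins["tibia"]):
            name = f"{pref}{sep}{lig}"
            e = params[name]
            seeds.append(LigamentBundle(
                name=name, ligament=lig,
                femur_point=np.asarray(fp, float),
                tibia_point=np.asarray(tp, float),
                stiffness=float(e["stiffness"]),
                ref_strain_pct=float(e["ref_strain_pct"]),
                wrap_surfaces=wrap))
        full = augment_bundles(seeds)
        if lig != "PCL":
            # printed table already carries the interpolated bundles' values
            full = [replace(b,
                            stiffness=float(params[b.name]["stiffness"]),
                            ref_strain_pct=float(params[b.name]["ref_strain_pct"]))
                    if b.name in params else b
                    for b in full]
        else:
            pcl_seed = seeds
        ligaments[lig] = full

    # measure reference lengths on this geometry, back-compute slack lengths
    for lig in ligaments:
        ligaments[lig] = _measure_reference_lengths(ligaments[lig], wrap_spheres)

    if calibrate and pcl_seed:
        pcl_seed = _measure_reference_lengths(pcl_seed, wrap_spheres)
        all_bundles = [b for lig in ligaments.values() for b in lig] + pcl_seed
        pose, _ = _distraction_pose(all_bundles, wrap_spheres)
        ligaments["PCL"] = calibrate_stiffness(
            pcl_seed, ligaments["PCL"], pose, wrap_spheres, law)

    lig_set = LigamentSet(ligaments, law, wrap_spheres)
    lig_set.validate_final_model()
    return lig_set
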