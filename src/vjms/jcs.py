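"""Grood-Suntay joint coordinate system kinematics.

The knee's relative pose is described by three rotations about a
body-fixed/floating axis triad — flexion about the femoral flexion axis,
axial rotation about the tibial long axis, ad/abduction about the mutually
perpendicular floating axis — and three translations along those axes.

Sign conventions (right knee): flexion positive; varus positive / valgus
negative; tibial external rotation positive / internal negative; anterior
tibial translation positive / posterior negative; lateral and superior
translations positive. All six coordinates are zero at the reference pose
(knee fully extended).

With the femoral flexion axis along the body z axis and the tibial long
axis along the body y axis, the relative rotation decomposes exactly as an
intrinsic z-x-y factorization M = Rz(a) Rx(b) Ry(c) with flexion = -a,
varus-valgus = b, internal(+ y)/external = -c.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AnatomicalFrames",
    "JcsCoordinates",
    "to_jcs",
    "from_jcs",
    "laxity",
    "relative_to_baseline",
]

DOF_NAMES = ("FE", "VV", "IE", "AP", "ML", "IS")


class KinematicsError(ValueError):
    pass


@dataclass
class AnatomicalFrames:
    """Body-fixed anatomical axes, both expressed at the reference pose.

    ``femur_axes`` / ``tibia_axes`` are 3x3 matrices whose columns are the
    anatomical x (anterior), y (long/proximal) and z (flexion/lateral) axes
    in each body's frame; origins are the shared joint centre at reference.
    For the synthetic geometry both default to the identity: the femoral
    flexion axis is the posterior condylar axis direction (body z) and the
    tibial long axis is the tray normal (body y).
    """

    femur_axes: np.ndarray = field(default_factory=lambda: np.eye(3))
    tibia_axes: np.ndarray = field(default_factory=lambda: np.eye(3))
    femur_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    tibia_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    handedness: float = 1.0   # +1 right knee, -1 left knee

    def __post_init__(self):
        for A in (self.femur_axes, self.tibia_axes):
            if not np.allclose(A @ A.T, np.eye(3), atol=1e-9) \
                    or np.linalg.det(A) < 0:
                raise KinematicsError("anatomical axes must be right-handed "
                                      "orthonormal")


@dataclass(frozen=True)
class JcsCoordinates:
    """Six Grood-Suntay coordinates (degrees / mm)."""

    FE: float   # flexion(+) / extension(-)
    VV: float   # varus(+) / valgus(-), right knee
    IE: float   # tibial external(+) / internal(-)
    AP: float   # anterior(+) / posterior(-)
    ML: float   # lateral(+)
    IS: float   # superior(+)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in DOF_NAMES}

    def __getitem__(self, key: str) -> float:
        return getattr(self, key)


def _apply(pose: np.ndarray, p: np.ndarray) -> np.ndarray:
    return pose[:3, :3] @ p + pose[:3, 3]


def to_jcs(femur_pose: np.ndarray, tibia_pose: np.ndarray,
           frames: AnatomicalFrames | None = None) -> JcsCoordinates:
    """Convert a rigid pose pair to Grood-Suntay coordinates."""
    frames = frames or AnatomicalFrames()
    Af = femur_pose[:3, :3] @ frames.femur_axes
    At = tibia_pose[:3, :3] @ frames.tibia_axes
    M = Af.T @ At
    s = frames.handedness
    # intrinsic z-x-y factorization M = Rz(a) Rx(b) Ry(c)
    sb = np.clip(M[2, 1], -1.0, 1.0)
    b = np.arcsin(sb)
    if abs(abs(b) - np.pi / 2) < 1e-9:
        raise KinematicsError("gimbal degeneracy: |ad-abduction| = 90 deg")
    a = np.arctan2(-M[0, 1], M[1, 1])
    c = np.arctan2(-M[2, 0], M[2, 2])
    fe = -np.degrees(a)
    vv = s * np.degrees(b)
    ie = -s * np.degrees(c)

    e1 = Af[:, 2]                      # femoral flexion axis (lateral)
    e3 = At[:, 1]                      # tibial long axis (proximal)
    H = _apply(tibia_pose, frames.tibia_origin) \
        - _apply(femur_pose, frames.femur_origin)
    e2 = np.cross(e3, e1)
    e2 = e2 / np.linalg.norm(e2)       # floating axis, anterior at reference
    return JcsCoordinates(
        FE=float(fe), VV=float(vv), IE=float(ie),
        AP=float(H @ e2), ML=float(s * (H @ e1)), IS=float(H @ e3))


def _rx(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _ry(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rz(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def from_jcs(coords: JcsCoordinates, femur_pose: np.ndarray,
             frames: AnatomicalFrames | None = None) -> np.ndarray:
    """Reconstruct the tibial pose from coordinates and the femoral pose."""
    frames = frames or AnatomicalFrames()
    s = frames.handedness
    a = -np.radians(coords.FE)
    b = s * np.radians(coords.VV)
    c = -s * np.radians(coords.IE)
    M = _rz(a) @ _rx(b) @ _ry(c)
    Af = femur_pose[:3, :3] @ frames.femur_axes
    Rt = Af @ M @ frames.tibia_axes.T
    e1 = Af[:, 2]
    e3 = (Rt @ frames.tibia_axes)[:, 1]
    e2 = np.cross(e3, e1)
    e2 = e2 / np.linalg.norm(e2)
    # the translation components are projections onto a non-orthogonal
    # triad; invert the projection exactly
    E = np.column_stack([e2, s * e1, e3])
    H = np.linalg.solve(E.T, np.array([coords.AP, coords.ML, coords.IS]))
    tibia_pose = np.eye(4)
    tibia_pose[:3, :3] = Rt
    tibia_pose[:3, 3] = (_apply(femur_pose, frames.femur_origin) + H
                         - Rt @ frames.tibia_origin)
    return tibia_pose


def laxity(neutral: JcsCoordinates, loaded: JcsCoordinates,
           dof: str, flexion_tol: float = 0.01) -> float:
    """Absolute kinematic difference |loaded - neutral| in one DOF.

    Both states must be at the same prescribed flexion angle.
    """
    if dof not in DOF_NAMES:
        raise KinematicsError(f"unknown DOF {dof!r}")
    if abs(loaded.FE - neutral.FE) > flexion_tol:
        raise KinematicsError(
            f"flexion mismatch: {neutral.FE:.3f} vs {loaded.FE:.3f} deg")
    return abs(loaded[dof] - neutral[dof])


def relative_to_baseline(kinematics: pd.DataFrame,
                         baseline_condition: str = "baseline",
                         neutral_test: str = "neutral",
                         dofs: tuple[str, ...] = DOF_NAMES) -> pd.DataFrame:
    """Express kinematics relative to the baseline neutral-flexion curve.

    Subtracts, per flexion angle, the baseline condition's neutral-flexion
    trajectory from every condition/test curve. Requires every flexion
    angle in the table to be present in the baseline neutral run.
    """
    base = kinematics[(kinematics["condition"] == baseline_condition)
                      & (kinematics["test"] == neutral_test)]
    if base.empty:
        raise KinematicsError("baseline neutral-flexion trajectory missing")
    ref = base.set_index("flexion_deg")[list(dofs)]
    missing = set(kinematics["flexion_deg"]) - set(ref.index)
    if missing:
        raise KinematicsError(
            f"baseline lacks flexion angles {sorted(missing)}")
    out = kinematics.copy()
    for dof in dofs:
        out[dof] = (kinematics[dof].to_numpy()
                    - ref[dof].reindex(kinematics["flexion_deg"]).to_numpy())
    return out
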