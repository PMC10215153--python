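"""Quasi-static equilibrium solver over the joint simulator's DOF set.

The simulator architecture splits the six knee DOFs between the bodies:
the femur can flex-extend and ad-abduct only; the tibia can translate in
three directions and rotate about its long axis. Each DOF is either
prescribed (displacement control) or driven to a target generalized load
(force control). A laxity protocol prescribes the flexion angle and leaves
everything else load-controlled.

Equilibrium is found by a damped quasi-Newton iteration on the free DOFs
with a finite-difference Jacobian, steps capped at 2 mm / 2 deg, and
residual tolerances of 0.5 N on forces and 50 N*mm on moments. The system
is conservative (nonlinear elastic fibers + penalty contact, no friction at
rest), so the iteration is deterministic and the converged states satisfy
an energy-work balance along quasi-static load sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .contact import (DEFAULT_PENALTY_STIFFNESS, ContactModel, ContactSummary,
                      contact_energy, contact_loads)
from .geometry import KneeGeometry, rotation_about
from .jcs import AnatomicalFrames, JcsCoordinates, to_jcs
from .ligaments import LigamentSet, ligament_loads, total_ligament_energy

__all__ = [
    "DOF_ORDER",
    "JointState",
    "DofSpec",
    "KneeModel",
    "EquilibriumSolution",
    "generalized_loads",
    "solve_equilibrium",
    "neutral_flexion",
    "FORCE_TOL",
    "MOMENT_TOL",
]

#: simulator DOFs: femur flexion-extension and ad-abduction; tibial
#: anterior-posterior / inferior-superior / medial-lateral translation and
#: internal-external rotation. Angles in degrees, translations in mm.
DOF_ORDER = ("flexion", "femur_aa", "tibia_ap", "tibia_is", "tibia_ml",
             "tibia_ie")
_ANGULAR = {"flexion", "femur_aa", "tibia_ie"}

FORCE_TOL = 0.5      # N
MOMENT_TOL = 50.0    # N*mm
MAX_STEP = 2.0       # mm or deg per Newton step
MAX_ITER = 500


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class JointState:
    """The six simulator DOF values (deg / mm)."""

    flexion: float = 0.0
    femur_aa: float = 0.0
    tibia_ap: float = 0.0
    tibia_is: float = 0.0
    tibia_ml: float = 0.0
    tibia_ie: float = 0.0

    def vector(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in DOF_ORDER])

    @staticmethod
    def from_vector(q: np.ndarray) -> "JointState":
        return JointState(**dict(zip(DOF_ORDER, map(float, q))))


@dataclass(frozen=True)
class DofSpec:
    """Control mode per DOF: prescribed value or target generalized load.

    ``prescribed`` maps DOF name -> value (deg/mm); ``targets`` maps DOF
    name -> applied load (N for translations, N*mm for rotations). DOFs
    missing from both dicts are load-controlled at zero (unconstrained).
    """

    prescribed: dict = field(default_factory=dict)
    targets: dict = field(default_factory=dict)

    def __post_init__(self):
        for k in (*self.prescribed, *self.targets):
            if k not in DOF_ORDER:
                raise SolverError(f"unknown DOF {k!r}")
        overlap = set(self.prescribed) & set(self.targets)
        if overlap:
            raise SolverError(f"DOFs both prescribed and load-controlled: "
                              f"{sorted(overlap)}")
        if not self.prescribed:
            raise SolverError("at least one DOF must be prescribed")

    @property
    def free(self) -> list:
        return [k for k in DOF_ORDER if k not in self.prescribed]

    def applied(self, dof: str) -> float:
        return float(self.targets.get(dof, 0.0))


@dataclass
class KneeModel:
    """Geometry + ligaments + contact for one malrotation condition."""

    geometry: KneeGeometry
    ligaments: LigamentSet
    penalty_stiffness: float = DEFAULT_PENALTY_STIFFNESS
    frames: AnatomicalFrames | None = None
    _contact: ContactModel | None = None

    def __post_init__(self):
        if self.frames is None:
            p = np.asarray(self.geometry.fe_axis_point, float)
            self.frames = AnatomicalFrames(femur_origin=p, tibia_origin=p)
        if self._contact is None:
            self._contact = ContactModel(self.geometry.component,
                                         self.geometry.insert)

    # -- kinematics ---------------------------------------------------
    def femur_pose(self, state: JointState) -> np.ndarray:
        p = np.asarray(self.geometry.fe_axis_point, float)
        aa = rotation_about(np.array([1.0, 0.0, 0.0]), np.zeros(3),
                            state.femur_aa)
        fe = rotation_about(np.array([0.0, 0.0, 1.0]), p, state.flexion)
        return aa @ fe

    def tibia_pose(self, state: JointState) -> np.ndarray:
        T = rotation_about(np.array([0.0, 1.0, 0.0]), np.zeros(3),
                           state.tibia_ie)
        T[:3, 3] += (state.tibia_ap, state.tibia_is, state.tibia_ml)
        return T

    def component_pose(self, state: JointState) -> np.ndarray:
        # the placement transform is baked into the placed component's mesh
        # and metadata, so the component rides the femur directly
        return self.femur_pose(state)

    def jcs(self, state: JointState) -> JcsCoordinates:
        return to_jcs(self.femur_pose(state), self.tibia_pose(state),
                      self.frames)

    # -- mechanics ----------------------------------------------------
    def loads(self, state: JointState):
        """Per-bundle and contact loads on the tibia at a state."""
        Tf = self.femur_pose(state)
        Tt = self.tibia_pose(state)
        lig_f, lig_m, per = ligament_loads(self.ligaments, Tf, Tt,
                                           moment_center=np.zeros(3))
        fld = self._contact.field(self.component_pose(state), Tt)
        summ = contact_loads(fld, self.penalty_stiffness,
                             moment_center=np.zeros(3))
        return lig_f, lig_m, per, fld, summ

    def total_energy(self, state: JointState) -> float:
        """Total elastic energy (ligaments + contact penalty), N*mm."""
        Tf = self.femur_pose(state)
        Tt = self.tibia_pose(state)
        e_lig = total_ligament_energy(self.ligaments, Tf, Tt)
        fld = self._contact.field(self.component_pose(state), Tt)
        return e_lig + contact_energy(fld, self.penalty_stiffness)


@dataclass
class EquilibriumSolution:
    state: JointState
    jcs: JcsCoordinates
    residuals: dict               # free DOF -> residual generalized load
    tensions: dict                # bundle -> N
    contact: ContactSummary
    converged: bool
    iterations: int
    generalized: dict             # all DOFs -> internal generalized load


def generalized_loads(model: KneeModel, state: JointState) -> dict:
    """Internal generalized loads (ligaments + contact) on each DOF.

    Tibial translations take the net world force components on the tibia;
    tibial rotation the moment about the tibia's long axis through its
    translated origin; femoral DOFs the moments of the equal-and-opposite
    load set on the femur about the ad-abduction (anterior) and flexion
    (lateral) axes.
    """
    lig_f, lig_m, per, fld, summ = model.loads(state)
    F = lig_f + summ.net_force               # on tibia, world
    M0 = lig_m + summ.net_moment             # about world origin
    t = np.array([state.tibia_ap, 0.0, state.tibia_ml])
    M_t = M0 - np.cross(t, F)                # about tibial axis point
    # femur-side loads: ligament loads are exactly minus the tibia's (two-
    # body statics of each fiber); contact reactions act at the hit points
    F_fem = -F
    M_fem0 = -lig_m + summ.femur_moment
    # the flexion axis rides the (outer) ad-abduction rotation
    aa = np.radians(state.femur_aa)
    ca, sa = np.cos(aa), np.sin(aa)
    R_aa = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    p_fe = R_aa @ np.asarray(model.geometry.fe_axis_point, float)
    fe_dir = R_aa @ np.array([0.0, 0.0, 1.0])
    M_fem_fe = M_fem0 - np.cross(p_fe, F_fem)
    return {
        "tibia_ap": float(F[0]),
        "tibia_is": float(F[1]),
        "tibia_ml": float(F[2]),
        "tibia_ie": float(M_t[1]),
        "femur_aa": float(M_fem0[0]),
        "flexion": float(M_fem_fe @ fe_dir),
    }


def _residual(model: KneeModel, spec: DofSpec, q: np.ndarray,
              free: list) -> np.ndarray:
    state = JointState.from_vector(q)
    g = generalized_loads(model, state)
    return np.array([g[d] + spec.applied(d) for d in free])


def _tolerances(free: list) -> np.ndarray:
    return np.array([MOMENT_TOL if d in _ANGULAR else FORCE_TOL
                     for d in free])


#: characteristic lever (mm) making rotational and translational DOFs
#: commensurate in the solver's scaled coordinates
_LEVER = 25.0
_ANG_SCALE = _LEVER * np.pi / 180.0     # scaled-mm per degree


def _potential(model: KneeModel, spec: DofSpec, q: np.ndarray) -> float:
    """Total potential: elastic energy minus work of the applied loads."""
    state = JointState.from_vector(q)
    pi = model.total_energy(state)
    for dof, target in spec.targets.items():
        val = q[DOF_ORDER.index(dof)]
        if dof in _ANGULAR:
            val = np.radians(val)
        pi -= target * val
    return pi


def solve_equilibrium(model: KneeModel, spec: DofSpec,
                      initial_guess: JointState | None = None,
                      max_iter: int = MAX_ITER,
                      fd_step: float = 0.02) -> EquilibriumSolution:
    """Damped Newton iteration to static equilibrium of the free DOFs.

    The system is conservative, so equilibrium is found by minimizing the
    total potential (elastic energy minus applied-load work): Newton steps
    on the residual with Levenberg regularization, an Armijo line search on
    the potential, and steps capped at 2 mm / 2 deg. Converged means every
    load-controlled DOF's internal generalized load balances its applied
    target within 0.5 N / 50 N*mm. On non-convergence the best state found
    is returned with ``converged=False``.
    """
    state0 = initial_guess or JointState()
    q = state0.vector()
    for dof, val in spec.prescribed.items():
        q[DOF_ORDER.index(dof)] = val
    free = spec.free
    idx = [DOF_ORDER.index(d) for d in free]
    tol = _tolerances(free)
    # scaled coordinates: angles in lever-equivalent mm
    xscale = np.array([_ANG_SCALE if d in _ANGULAR else 1.0 for d in free])
    # residual -> gradient of the potential in scaled coordinates
    gscale = np.array([1.0 / _LEVER if d in _ANGULAR else 1.0 for d in free])

    def scaled_norm(r):
        return float(np.max(np.abs(r) / tol)) if len(r) else 0.0

    r = _residual(model, spec, q, free)
    pi = _potential(model, spec, q)
    best = (scaled_norm(r), q.copy(), r.copy())
    iters = 0
    mu = 0.0
    while iters < max_iter and scaled_norm(r) > 1.0:
        iters += 1
        # forward-difference Jacobian of the residual on the free DOFs
        J = np.empty((len(free), len(free)))
        for j, qi in enumerate(idx):
            qp = q.copy()
            qp[qi] += fd_step
            J[:, j] = (_residual(model, spec, qp, free) - r) / fd_step
        # Hessian of the potential in scaled coordinates (symmetrized)
        H = -(gscale[:, None] * J / xscale[None, :])
        H = 0.5 * (H + H.T)
        grad = -r * gscale
        accepted = False
        for _ in range(12):
            try:
                step_x = np.linalg.solve(
                    H + mu * np.eye(len(free)), -grad)
            except np.linalg.LinAlgError:
                mu = max(10.0 * mu, 1.0)
                continue
            if step_x @ grad >= 0.0:       # not a descent direction
                mu = max(10.0 * mu, 1.0)
                continue
            step_q = step_x / xscale
            big = np.max(np.abs(step_q))
            if big > MAX_STEP:
                step_q *= MAX_STEP / big
                step_x = step_q * xscale
            # Armijo backtracking on the potential
            lam = 1.0
            for _ in range(10):
                q_try = q.copy()
                q_try[idx] += lam * step_q
                pi_try = _potential(model, spec, q_try)
                if pi_try <= pi + 1e-4 * lam * (step_x @ grad):
                    q = q_try
                    pi = pi_try
                    r = _residual(model, spec, q, free)
                    accepted = True
                    break
                lam *= 0.5
            if accepted:
                mu = mu * 0.25 if mu > 1e-8 else 0.0
                break
            mu = max(10.0 * mu, 1.0)
        if not accepted:
            break                           # cannot decrease the potential
        if scaled_norm(r) < best[0]:
            best = (scaled_norm(r), q.copy(), r.copy())

    if scaled_norm(r) > best[0]:
        _, q, r = best
    state = JointState.from_vector(q)
    g = generalized_loads(model, state)
    _, _, per, fld, summ = model.loads(state)
    if summ.net_compression <= 0.0 and all(
            p["tension"] == 0.0 for p in per.values()):
        raise SolverError("joint dislocated: no contact and all ligaments "
                          "slack")
    return EquilibriumSolution(
        state=state,
        jcs=model.jcs(state),
        residuals={d: float(rr) for d, rr in zip(free, r)},
        tensions={k: p["tension"] for k, p in per.items()},
        contact=summ,
        converged=bool(scaled_norm(r) <= 1.0),
        iterations=iters,
        generalized=g,
    )


def neutral_flexion(model: KneeModel, flexion_angles,
                    initial_guess: JointState | None = None,
                    targets: dict | None = None) -> list[EquilibriumSolution]:
    """Sequential equilibria through neutral flexion (flexion prescribed,
    all other DOFs load-controlled, default targets zero). Each converged
    state seeds the next angle (continuation)."""
    angles = list(flexion_angles)
    if any(b < a for a, b in zip(angles, angles[1:])):
        raise SolverError("flexion angles must be ascending")
    sols = []
    guess = initial_guess or JointState()
    prev = angles[0]
    for ang in angles:
        # sub-stepped continuation keeps each seed close to equilibrium
        n_sub = max(int(np.ceil(abs(ang - prev) / 7.5)), 1)
        for k in range(1, n_sub + 1):
            a = prev + (ang - prev) * k / n_sub
            spec = DofSpec(prescribed={"flexion": a}, targets=targets or {})
            sol = solve_equilibrium(model, spec, guess)
            if not sol.converged:
                raise SolverError(f"neutral flexion failed to converge at "
                                  f"{a} deg (residuals {sol.residuals})")
            guess = sol.state
        sols.append(sol)
        prev = ang
    return sols


def ramped_solve(model: KneeModel, flexion_deg: float, targets: dict,
                 seed: JointState, n_ramp: int = 4) -> EquilibriumSolution:
    """Laxity-test solve: ramp the applied loads to their targets in equal
    increments from the neutral equilibrium at the same flexion angle."""
    sol = None
    guess = seed
    for i in range(1, n_ramp + 1):
        frac = i / n_ramp
        spec = DofSpec(prescribed={"flexion": flexion_deg},
                       targets={k: v * frac for k, v in targets.items()})
        sol = solve_equilibrium(model, spec, guess)
        guess = sol.state
    return sol
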