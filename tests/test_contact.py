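import numpy as np
import pytest
import trimesh

from vjms.contact import (REG_DEPTH, ContactError, ContactModel,
                          contact_energy, contact_loads, penetration_field)
from vjms.geometry import SurfaceMesh, place_component

EYE = np.eye(4)


def _plane_insert(half=20.0, grid=2.0, label="insert"):
    """Flat articular block, top surface at y = 0."""
    n = int(2 * half / grid)
    x = np.linspace(-half, half, n + 1)
    z = np.linspace(-half, half, n + 1)
    X, Z = np.meshgrid(x, z, indexing="ij")
    top = np.stack([X, np.zeros_like(X), Z], -1).reshape(-1, 3)
    bot = top + np.array([0.0, -5.0, 0.0])
    nv = len(top)
    faces = []
    for i in range(n):
        for j in range(n):
            a = i * (n + 1) + j
            b = (i + 1) * (n + 1) + j
            faces += [[a, a + 1, b], [a + 1, b + 1, b]]     # normals +y
            a2, b2 = a + nv, b + nv
            faces += [[a2, b2, a2 + 1], [a2 + 1, b2, b2 + 1]]
    mesh = trimesh.Trimesh(np.vstack([top, bot]), faces, process=False)
    return SurfaceMesh(mesh, label, {"grid": grid, "midline_z": 0.0})


def _sphere_component(radius=15.0, center_y=15.0, subdivisions=4):
    ball = trimesh.creation.icosphere(subdivisions=subdivisions,
                                      radius=radius)
    ball.apply_translation((0.0, center_y, 0.0))
    return SurfaceMesh(ball, "femoral_component", {})


class TestPenetrationField:
    def test_separated_bodies_zero_depth(self):
        comp = _sphere_component(center_y=20.0)   # 5 mm clearance
        field = penetration_field(comp, _plane_insert(), EYE, EYE)
        assert (field.depths == 0.0).all()

    def test_sphere_on_plane_pole_depth(self):
        """Sphere pressed depth d into a plane: max depth = d at the pole."""
        d = 0.8
        comp = _sphere_component(radius=15.0, center_y=15.0 - d)
        field = penetration_field(comp, _plane_insert(grid=1.0), EYE, EYE)
        imax = np.argmax(field.depths)
        assert field.depths[imax] == pytest.approx(d, abs=0.02)
        assert np.hypot(field.points[imax][0],
                        field.points[imax][2]) < 1.0

    def test_mirror_symmetric_pose(self):
        comp = _sphere_component(center_y=14.5)
        comp.mesh.apply_translation((0.0, 0.0, 6.0))
        field = penetration_field(comp, _plane_insert(grid=1.0), EYE, EYE)
        depths = {(round(p[0], 3), round(p[2], 3)): dd
                  for p, dd in zip(field.points, field.depths)}
        for (x, z), dd in depths.items():
            # the sphere at z = +6: field mirrored about z = 6
            mirror = (x, round(12.0 - z, 3))
            if mirror in depths:
                assert depths[mirror] == pytest.approx(dd, abs=1e-6)

    def test_empty_articular_surface_errors(self):
        # a surface whose every normal faces inferiorly has no articular side
        tri = trimesh.Trimesh([[0, 0, 0], [10, 0, 0], [0, 0, 10]],
                              [[0, 1, 2]], process=False)
        if tri.face_normals[0][1] > 0:
            tri.invert()
        with pytest.raises(ContactError):
            penetration_field(_sphere_component(),
                              SurfaceMesh(tri, "insert", {}), EYE, EYE)


class TestContactLoads:
    def test_zero_field_zero_summary(self):
        comp = _sphere_component(center_y=25.0)
        field = penetration_field(comp, _plane_insert(), EYE, EYE)
        s = contact_loads(field)
        assert s.net_compression == 0.0
        assert np.allclose(s.net_force, 0.0)
        assert s.max_penetration == 0.0

    def test_flat_on_flat_closed_form(self):
        """Uniform depth d over area A: net normal force equals
        k * (d - d0/2) * A with the activation-regularized pressure."""
        top = _plane_insert(half=10.0, grid=1.0)
        d = 0.5
        block = trimesh.creation.box(extents=(12.0, 4.0, 12.0))
        block.apply_translation((0.0, 2.0 - d, 0.0))
        comp = SurfaceMesh(block, "femoral_component", {})
        field = penetration_field(comp, top, EYE, EYE)
        k = 100.0
        s = contact_loads(field, penalty_stiffness=k)
        area = field.areas[field.depths > 0].sum()
        expected = k * (d - REG_DEPTH / 2) * area
        assert -s.net_force[1] == pytest.approx(expected, rel=1e-9)

    def test_compartment_conservation(self, baseline_model):
        from vjms.equilibrium import JointState
        st = JointState(flexion=30.0, tibia_is=0.3, femur_aa=-1.0)
        field = baseline_model._contact.field(
            baseline_model.component_pose(st),
            baseline_model.tibia_pose(st))
        s = contact_loads(field)
        total_is = -(s.net_force @ field.is_axis)
        assert s.medial_force + s.lateral_force == pytest.approx(
            total_is, rel=1e-6)

    def test_coulomb_friction_magnitude(self):
        top = _plane_insert(half=10.0, grid=1.0)
        block = trimesh.creation.box(extents=(12.0, 4.0, 12.0))
        block.apply_translation((0.0, 1.5, 0.0))
        comp = SurfaceMesh(block, "femoral_component", {})
        field = penetration_field(comp, top, EYE, EYE)
        s0 = contact_loads(field, friction_coefficient=0.0)
        s = contact_loads(field, friction_coefficient=0.04,
                          sliding_direction=np.array([1.0, 0.0, 0.0]))
        normal = -s0.net_force[1]
        assert np.linalg.norm(s.tangential_force) == pytest.approx(
            0.04 * normal, rel=1e-9)

    def test_negative_stiffness_rejected(self):
        comp = _sphere_component()
        field = penetration_field(comp, _plane_insert(), EYE, EYE)
        with pytest.raises(ContactError):
            contact_loads(field, penalty_stiffness=-1.0)


class TestEngines:
    def test_analytic_matches_mesh_rays(self, base_geometry):
        """The torus-implicit engine and the triangle ray caster agree to
        the facet sag of the triangulation."""
        geom = place_component(base_geometry, "baseline")
        tib = np.eye(4)
        tib[1, 3] = 0.4
        fa = penetration_field(geom.component, geom.insert, EYE, tib,
                               engine="analytic")
        fm = penetration_field(geom.component, geom.insert, EYE, tib,
                               engine="mesh")
        both = (fa.depths > 0.05) & (fm.depths > 0.05)
        assert both.sum() > 50
        assert np.abs(fa.depths[both] - fm.depths[both]).max() < 0.03
        sa = contact_loads(fa)
        sm = contact_loads(fm)
        # wall-slope normals differ by the facet angle, so the force match
        # is looser than the depth match
        assert sa.net_compression == pytest.approx(sm.net_compression,
                                                   rel=0.08)

    def test_refinement_convergence_sphere_on_dish(self):
        """Doubling the articular sampling density changes the net contact
        force by < 2 % for a sphere-on-dish fixture."""
        def dish(grid):
            sm = _plane_insert(half=20.0, grid=grid)
            v = sm.mesh.vertices.copy()
            top = v[:, 1] > -1.0
            r2 = v[top, 0] ** 2 + v[top, 2] ** 2
            v[top, 1] = r2 / (2 * 40.0)          # parabolic dish, R ~ 40
            sm.mesh.vertices = v
            return SurfaceMesh(sm.mesh, "insert", {"midline_z": 0.0})

        comp = _sphere_component(radius=15.0, center_y=14.7)
        forces = []
        for grid in (1.0, 0.5):
            f = penetration_field(comp, dish(grid), EYE, EYE)
            forces.append(contact_loads(f).net_compression)
        assert abs(forces[1] - forces[0]) / forces[1] < 0.02

    def test_energy_is_force_integral(self):
        """Contact energy equals the integral of the net vertical force
        over an approach sweep (trapezoid oracle)."""
        comp = _sphere_component(radius=15.0, center_y=15.0)
        insert = _plane_insert(half=12.0, grid=1.0)
        model = ContactModel(comp, insert)
        dys = np.linspace(0.0, 0.6, 61)
        forces, energies = [], []
        for dy in dys:
            tib = np.eye(4)
            tib[1, 3] = dy
            f = model.field(EYE, tib)
            forces.append(-(contact_loads(f).net_force[1]))
            energies.append(contact_energy(f))
        work = np.trapezoid(forces, dys)
        assert energies[-1] == pytest.approx(work, rel=2e-3)
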