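import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vjms.geometry import WrapSphere
from vjms.ligaments import (FiberForceLaw, LigamentBundle, LigamentError,
                            augment_bundles, build_ligament_set,
                            calibrate_stiffness, fiber_energy, fiber_tension,
                            ligament_loads, load_parameter_table,
                            reference_strain, slack_length, wrap_path)

EYE = np.eye(4)


def _bundle(name="m-sMCL", ligament="sMCL", fem=(0, 50, 0), tib=(0, -50, 0),
            k=1000.0, eps_r=0.0, wrap=()):
    return LigamentBundle(name=name, ligament=ligament,
                          femur_point=np.array(fem, float),
                          tibia_point=np.array(tib, float),
                          stiffness=k, ref_strain_pct=eps_r,
                          wrap_surfaces=wrap)


def _with_lengths(b, wrap_spheres=()):
    from vjms.ligaments import _measure_reference_lengths
    return _measure_reference_lengths([b], list(wrap_spheres))[0]


class TestStrainBookkeeping:
    def test_zero_strain_identity(self):
        assert reference_strain(40.0, 40.0) == 0.0

    def test_direct_formula(self):
        assert reference_strain(52.0, 50.0) == pytest.approx(4.0)
        assert slack_length(52.0, 4.0) == pytest.approx(50.0)

    @given(l_r=st.floats(1.0, 200.0),
           eps=st.floats(-60.0, 60.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_roundtrip_identity(self, l_r, eps):
        l_0 = slack_length(l_r, eps)
        assert reference_strain(l_r, l_0) == pytest.approx(eps, abs=1e-9,
                                                           rel=1e-9)

    def test_domain_errors(self):
        with pytest.raises(LigamentError):
            reference_strain(40.0, 0.0)
        with pytest.raises(LigamentError):
            slack_length(40.0, -100.0)


class TestFiberForceLaw:
    def test_slack_fiber_carries_nothing(self):
        assert fiber_tension(-0.05, 1000.0) == 0.0
        assert fiber_tension(0.0, 1000.0) == 0.0

    def test_toe_linear_junction_continuity(self):
        k, t = 1000.0, 0.03
        assert fiber_tension(2 * t, k, t) == pytest.approx(k * t)
        eps = 1e-8
        below = fiber_tension(2 * t - eps, k, t)
        above = fiber_tension(2 * t + eps, k, t)
        assert above - below == pytest.approx(0.0, abs=1e-3)
        # C1: slopes agree at the junction
        h = 1e-7
        slope_lo = (fiber_tension(2 * t, k, t)
                    - fiber_tension(2 * t - h, k, t)) / h
        slope_hi = (fiber_tension(2 * t + h, k, t)
                    - fiber_tension(2 * t, k, t)) / h
        assert slope_lo == pytest.approx(slope_hi, rel=1e-4)

    def test_linear_branch_value(self):
        assert fiber_tension(0.10, 1000.0, 0.03) == pytest.approx(70.0)

    def test_monotone_nondecreasing(self):
        eps = np.linspace(-0.1, 0.5, 2001)
        f = fiber_tension(eps, 1481.0)
        assert (np.diff(f) >= -1e-12).all()

    def test_energy_is_tension_integral(self):
        k, l0 = 1481.0, 78.0
        grid = np.linspace(0.0, 0.2, 40001)
        brute = np.trapezoid(fiber_tension(grid, k), grid) * l0
        assert fiber_energy(0.2, k, l0) == pytest.approx(brute, rel=1e-6)


class TestAugmentation:
    def make_collateral(self, strains=(-2.66, 4.02, 1.29), ks=(1157, 1175, 1182)):
        pts = [(0, 50, z) for z in (-2.0, 0.0, 2.0)]
        return [_bundle(n, "LCL", fem=p, tib=(0, -50, 0), k=k, eps_r=s)
                for n, p, k, s in zip(("aLCL", "mLCL", "pLCL"), pts, ks,
                                      strains)]

    def test_printed_lcl_interpolations(self):
        out = augment_bundles(self.make_collateral())
        names = [b.name for b in out]
        assert names == ["aLCL", "amLCL", "mLCL", "mpLCL", "pLCL"]
        by = {b.name: b for b in out}
        # agreement with the printed two-decimal values (half an ulp slack:
        # the mean of the neighbours is exactly 2.655)
        assert by["amLCL"].ref_strain_pct == pytest.approx(0.68, abs=0.0051)
        assert by["mpLCL"].ref_strain_pct == pytest.approx(2.66, abs=0.0051)

    def test_printed_smcl_interpolations(self):
        seeds = [_bundle("a-sMCL", eps_r=-4.30), _bundle("m-sMCL", eps_r=4.50),
                 _bundle("p-sMCL", eps_r=4.44)]
        out = augment_bundles(seeds)
        by = {b.name: b for b in out}
        assert by["am-sMCL"].ref_strain_pct == pytest.approx(0.10, abs=0.0051)
        assert by["mp-sMCL"].ref_strain_pct == pytest.approx(4.47, abs=0.0051)

    def test_midpoint_insertions(self):
        out = augment_bundles(self.make_collateral())
        by = {b.name: b for b in out}
        assert np.allclose(by["amLCL"].femur_point,
                           0.5 * (by["aLCL"].femur_point
                                  + by["mLCL"].femur_point))

    def test_pcl_two_to_three(self):
        seeds = [_bundle("aPCL", "PCL", eps_r=-28.6, k=7841),
                 _bundle("pPCL", "PCL", eps_r=-26.3, k=1026)]
        out = augment_bundles(seeds)
        assert [b.name for b in out] == ["aPCL", "mPCL", "pPCL"]
        assert out[1].ref_strain_pct == pytest.approx(-27.45)

    def test_degenerate_midpoint(self):
        seeds = [_bundle("aPCL", "PCL", eps_r=3.0),
                 _bundle("pPCL", "PCL", eps_r=3.0)]
        out = augment_bundles(seeds)
        assert np.allclose(out[1].femur_point, seeds[0].femur_point)
        assert out[1].ref_strain_pct == 3.0

    def test_too_few_bundles(self):
        with pytest.raises(LigamentError):
            augment_bundles([_bundle()])


class TestCalibration:
    def distraction(self, mm=10.0):
        pose = np.eye(4)
        pose[1, 3] = -mm
        return (np.eye(4), pose)

    def test_identity_when_nothing_added(self):
        orig = [_with_lengths(_bundle(eps_r=2.0))]
        out = calibrate_stiffness(orig, orig, self.distraction())
        assert out[0].stiffness == pytest.approx(orig[0].stiffness)

    def test_split_parallel_bundles_conserves_tension(self):
        """Two identical parallel fibers split into three: total tension at
        the distracted pose is conserved (closed-form sum of linear
        springs gives the 2/3 stiffness factor)."""
        pair = [_with_lengths(_bundle(n, eps_r=4.0, k=600.0))
                for n in ("aPCL", "pPCL")]
        triple = [_with_lengths(_bundle(n, eps_r=4.0, k=600.0))
                  for n in ("aPCL", "mPCL", "pPCL")]
        out = calibrate_stiffness(pair, triple, self.distraction())
        assert all(b.stiffness == pytest.approx(400.0) for b in out)
        law = FiberForceLaw()
        for dist in (6.0, 10.0, 14.0):
            fe, ti = self.distraction(dist)
            def total(bs):
                t = 0.0
                for b in bs:
                    L = np.linalg.norm(
                        (b.tibia_point + ti[:3, 3]) - b.femur_point)
                    t += law.tension((L - b.slack_length_mm)
                                     / b.slack_length_mm, b.stiffness)
                return t
            assert total(out) == pytest.approx(total(pair), rel=1e-9)

    def test_uniform_scale_factor(self):
        """200 N original vs 250 N nominal augmented -> factor 0.8."""
        orig = [_with_lengths(_bundle("aPCL", k=1000.0, eps_r=5.0))]
        aug = [_with_lengths(_bundle("aPCL", k=1250.0, eps_r=5.0))]
        out = calibrate_stiffness(orig, aug, self.distraction())
        assert out[0].stiffness == pytest.approx(1000.0)
        ratio = out[0].stiffness / aug[0].stiffness
        assert ratio == pytest.approx(0.8)

    def test_slack_bundle_rejected(self):
        slack = _with_lengths(_bundle(eps_r=-50.0))
        with pytest.raises(LigamentError):
            calibrate_stiffness([slack], [slack], self.distraction(1.0))


class TestWrapping:
    SPHERE = WrapSphere("bump", (0.0, 0.0, 0.0), 10.0)

    def test_clear_segment_is_straight(self):
        b = _bundle(fem=(30, 50, 0), tib=(30, -50, 0), wrap=("bump",))
        res = wrap_path(b, [self.SPHERE], EYE, EYE)
        assert not res.wrapped
        assert res.length == pytest.approx(100.0)

    def test_symmetric_wrap_matches_plane_construction(self):
        """Symmetric endpoints: the single-bend path equals the independent
        2-D tangent-intersection construction in the wrap plane."""
        a, d, r = 40.0, 4.0, 10.0
        b = _bundle(fem=(-a, d, 0), tib=(a, d, 0), wrap=("bump",))
        res = wrap_path(b, [self.SPHERE], EYE, EYE)
        assert res.wrapped
        # independent 2-D construction: tangent from (-a, d) to circle r,
        # intersected with the vertical symmetry axis
        alpha = math.acos(r / math.hypot(a, d))    # tangent angle
        beta = math.atan2(d, -a)                   # angle of A from centre
        phi = beta - alpha                         # tangent point angle
        px, py = r * math.cos(phi), r * math.sin(phi)
        # line A->P meets x = 0 at the bend point
        t = (0.0 - (-a)) / (px - (-a))
        vy = d + t * (py - d)
        expected = 2.0 * math.hypot(a, vy - d)
        assert res.length == pytest.approx(expected, rel=1e-9)
        assert abs(res.points[1][0]) < 1e-9        # bend on symmetry plane

    def test_wrapped_longer_than_chord(self):
        b = _bundle(fem=(-40, 4, 0), tib=(40, 4, 0), wrap=("bump",))
        res = wrap_path(b, [self.SPHERE], EYE, EYE)
        chord = 80.0
        assert res.length > chord

    def test_zero_residual_penetration(self):
        """100 samples along each sub-segment stay outside the sphere."""
        b = _bundle(fem=(-40, 4, 3), tib=(40, 2, -5), wrap=("bump",))
        res = wrap_path(b, [self.SPHERE], EYE, EYE)
        assert res.wrapped
        c = np.array(self.SPHERE.center)
        for p0, p1 in zip(res.points[:-1], res.points[1:]):
            ts = np.linspace(0, 1, 100)[:, None]
            pts = p0 + ts * (p1 - p0)
            dist = np.linalg.norm(pts - c, axis=1)
            assert (dist >= self.SPHERE.radius - 1e-9).all()

    def test_insertion_inside_sphere_errors(self):
        b = _bundle(fem=(0, 5, 0), tib=(0, -50, 0), wrap=("bump",))
        with pytest.raises(LigamentError):
            wrap_path(b, [self.SPHERE], EYE, EYE)

    def test_wrap_moves_with_tibia(self):
        """The wrap sphere is tibia-fixed: translating the tibia moves the
        bend point accordingly."""
        b = _bundle(fem=(-40, 4, 0), tib=(40, 4, 0), wrap=("bump",))
        r0 = wrap_path(b, [self.SPHERE], EYE, EYE)
        shifted = np.eye(4)
        shifted[0, 3] = 5.0
        r1 = wrap_path(b, [self.SPHERE], EYE, shifted)
        assert r1.points[1][0] > r0.points[1][0]


class TestLigamentLoads:
    def _set(self, bundles):
        from vjms.ligaments import LigamentSet
        return LigamentSet({"sMCL": bundles}, FiberForceLaw(), [])

    def test_all_slack_zero_loads(self):
        b = _with_lengths(_bundle(eps_r=-50.0))
        f, m, per = ligament_loads(self._set([b]), EYE, EYE)
        assert np.allclose(f, 0) and np.allclose(m, 0)
        assert per[b.name]["tension"] == 0.0

    def test_single_vertical_bundle_statics(self):
        b = _with_lengths(_bundle(fem=(0, 50, 0), tib=(0, -50, 0),
                                  eps_r=0.0, k=1000.0))
        drop = np.eye(4)
        drop[1, 3] = -10.0     # stretch by 10 mm -> strain 0.1
        f, m, per = ligament_loads(self._set([b]), EYE, drop,
                                   moment_center=np.array([0.0, 50.0, 0.0]))
        expected = 1000.0 * (10.0 / b.slack_length_mm - 0.03)
        assert per[b.name]["tension"] == pytest.approx(expected, rel=1e-9)
        assert f[1] == pytest.approx(expected, rel=1e-9)
        assert abs(f[0]) < 1e-9 and abs(f[2]) < 1e-9
        assert np.allclose(m, 0, atol=1e-9)

    def test_mirrored_collaterals_cancel_vv_moment(self):
        med = _with_lengths(_bundle("m-sMCL", fem=(0, 40, -30),
                                    tib=(0, -40, -30), eps_r=5.0))
        lat = _with_lengths(_bundle("mLCL", fem=(0, 40, 30),
                                    tib=(0, -40, 30), eps_r=5.0))
        f, m, per = ligament_loads(self._set([med, lat]), EYE, EYE)
        assert m[0] == pytest.approx(0.0, abs=1e-9)   # varus-valgus
        assert f[2] == pytest.approx(0.0, abs=1e-9)   # medial-lateral


class TestModelAssembly:
    def test_final_model_composition(self, ligament_set):
        counts = {k: len(v) for k, v in ligament_set.ligaments.items()}
        assert counts == {"sMCL": 5, "LCL": 5, "PCL": 3}
        for b in ligament_set.ligaments["sMCL"]:
            assert "tibia_wrap_medial" in b.wrap_surfaces

    def test_reference_strain_consistency(self, ligament_set):
        for b in ligament_set.bundles():
            implied = reference_strain(b.ref_length_mm, b.slack_length_mm)
            assert implied == pytest.approx(b.ref_strain_pct, abs=1e-9)

    def test_table_values_carried(self, ligament_set):
        table = {e["name"]: e for e in load_parameter_table()["bundles"]}
        for b in ligament_set.bundles():
            if b.name in table and b.ligament != "PCL":
                assert b.stiffness == table[b.name]["stiffness"]
                assert b.ref_strain_pct == table[b.name]["ref_strain_pct"]

    def test_pcl_calibration_conserves_distracted_tension(self,
                                                          base_geometry):
        """The 3-bundle PCL carries the same total tension as the printed
        2-bundle PCL at the fully engaging distracted pose."""
        from vjms.ligaments import (_distraction_pose,
                                    _measure_reference_lengths)
        table = load_parameter_table()
        params = {e["name"]: e for e in table["bundles"]}
        ins = base_geometry.insertions["PCL"]
        seeds = [_bundle(n, "PCL", fem=f, tib=t,
                         k=params[n]["stiffness"],
                         eps_r=params[n]["ref_strain_pct"])
                 for n, f, t in zip(("aPCL", "pPCL"), ins["femur"],
                                    ins["tibia"])]
        seeds = _measure_reference_lengths(seeds, base_geometry.wrap_spheres)
        final = build_ligament_set(base_geometry).ligaments["PCL"]
        everything = seeds + final
        pose, _ = _distraction_pose(everything, base_geometry.wrap_spheres)
        law = FiberForceLaw()

        def total(bundles):
            tot = 0.0
            for b in bundles:
                L = wrap_path(b, base_geometry.wrap_spheres, *pose).length
                tot += law.tension((L - b.slack_length_mm)
                                   / b.slack_length_mm, b.stiffness)
            return tot

        assert total(final) == pytest.approx(total(seeds), rel=1e-6)

    def test_smcl_wraps_at_reference(self, ligament_set):
        wrapped = [wrap_path(b, ligament_set.wrap_spheres, EYE, EYE).wrapped
                   for b in ligament_set.ligaments["sMCL"]]
        assert all(wrapped)
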