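"""Idealized LV chamber: geometry volumes against closed forms, fibre
field, AHA labelling, incompressible kinematics and the wall force
balance against its one-fibre closed form."""

import numpy as np
import pytest

from stenosim.chamber import (GeometryError, InvalidVolumeError,
                              LVGeometryParams, aha_segment, build_geometry,
                              cavity_pressure, cavity_pressure_from_fiber_tension,
                              kinematics, lv_pressure_and_stress,
                              truncated_ellipsoid_volume)
from stenosim.materials.active import ActiveParameters
from stenosim.materials.passive import HOParameters


class TestGeometry:
    def test_equator_truncation_is_half_volume(self):
        a, c = 24.0, 60.0
        full = 4.0 / 3.0 * np.pi * a * a * c
        assert truncated_ellipsoid_volume(a, c, 0.0) == pytest.approx(full / 2)
        assert truncated_ellipsoid_volume(a, c, c) == pytest.approx(full)

    def test_weights_sum_to_analytic_wall_volume(self, model):
        p = model.params
        analytic = (truncated_ellipsoid_volume(
            p.a_endo + p.wall_thickness, p.c_endo + p.apex_thickness, p.h_base)
            - truncated_ellipsoid_volume(p.a_endo, p.c_endo, p.h_base))
        assert model.weight.sum() == pytest.approx(analytic, rel=5e-3)
        assert model.weight.sum() == pytest.approx(model.wall_volume, rel=1e-12)

    def test_refinement_consistency(self, model):
        p = model.params
        fine = build_geometry(LVGeometryParams(
            a_endo=p.a_endo, c_endo=p.c_endo, wall_thickness=p.wall_thickness,
            apex_thickness=p.apex_thickness, h_base=p.h_base,
            n_transmural=2 * p.n_transmural,
            n_longitudinal=2 * p.n_longitudinal,
            n_circumferential=2 * p.n_circumferential), seed=1)
        assert fine.wall_volume == pytest.approx(model.wall_volume, rel=1e-3)
        # volume-weighted mean of a depth-dependent field is mesh-invariant
        for m in (model, fine):
            m.mean_lr = np.average(m.lr, weights=m.weight)
        assert fine.mean_lr == pytest.approx(model.mean_lr, rel=0.02)

    def test_every_aha_segment_populated(self, model):
        assert set(np.unique(model.segment)) == set(range(1, 18))

    def test_fiber_frame_orthonormal_and_right_handed(self, model):
        f0, s0, n0 = model.f0, model.s0, model.n0
        assert np.allclose(np.linalg.norm(f0, axis=1), 1.0, atol=1e-9)
        assert np.allclose(np.einsum("ij,ij->i", f0, s0), 0.0, atol=1e-9)
        assert np.allclose(np.cross(f0, s0), n0, atol=1e-9)

    def test_fiber_angle_rule(self, model):
        """Helix angle runs +60 deg (endo) to -60 deg (epi), measured
        from the local circumferential direction."""
        phi = np.arctan2(model.position[:, 1], model.position[:, 0])
        e_c = np.column_stack([-np.sin(phi), np.cos(phi), np.zeros(len(phi))])
        # remove the transmural component of e_c before comparing
        e_c -= np.einsum("ij,ij->i", e_c, model.n0)[:, None] * model.n0
        e_c /= np.linalg.norm(e_c, axis=1)[:, None]
        cosang = np.clip(np.einsum("ij,ij->i", model.f0, e_c), -1, 1)
        expected = np.radians(60.0 - 120.0 * model.depth)
        assert np.allclose(np.abs(np.cos(expected)), np.abs(cosang), atol=1e-6)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(GeometryError):
            LVGeometryParams(wall_thickness=-1.0)
        with pytest.raises(GeometryError):
            LVGeometryParams(h_base=80.0)
        with pytest.raises(GeometryError):
            LVGeometryParams(n_transmural=1)

    def test_deterministic_for_seed(self):
        a = build_geometry(seed=3)
        b = build_geometry(seed=3)
        assert np.array_equal(a.position, b.position)
        assert np.array_equal(a.segment, b.segment)


class TestAhaSegments:
    PARAMS = LVGeometryParams()

    def test_apex_cap(self):
        z_apex = -(self.PARAMS.c_endo + self.PARAMS.apex_thickness)
        assert aha_segment(np.array([1.0, 0.0, z_apex + 1.0]),
                           self.PARAMS) == 17

    def test_basal_anterior(self):
        # anterior (phi = 90 deg) at basal height -> segment 1
        assert aha_segment(np.array([0.0, 25.0, self.PARAMS.h_base - 1.0]),
                           self.PARAMS) == 1

    def test_sector_rotation_increments_basal_labels(self):
        z = self.PARAMS.h_base - 1.0
        labels = []
        for k in range(6):
            phi = np.radians(90.0 + 60.0 * k)
            labels.append(aha_segment(
                np.array([25 * np.cos(phi), 25 * np.sin(phi), z]),
                self.PARAMS))
        assert labels == [1, 2, 3, 4, 5, 6]


class TestKinematics:
    def test_reference_volume_is_identity(self, model):
        ws = kinematics(model, model.cavity_volume)
        assert np.allclose(ws.F, np.eye(3)[None], atol=1e-12)
        assert np.allclose(ws.Eff, 0.0, atol=1e-14)

    def test_exact_incompressibility(self, model):
        for V in (0.6, 0.9, 1.1, 1.4):
            ws = kinematics(model, V * model.cavity_volume)
            assert np.abs(np.linalg.det(ws.F) - 1.0).max() < 1e-10

    def test_endocardium_stretches_more_on_inflation(self, model):
        ws = kinematics(model, 1.3 * model.cavity_volume)
        endo = ws.Eff[model.depth < 0.15].mean()
        epi = ws.Eff[model.depth > 0.85].mean()
        assert ws.Eff.mean() > 0
        assert endo > epi

    def test_invalid_volume(self, model):
        with pytest.raises(InvalidVolumeError):
            kinematics(model, -10.0)


class TestForceBalance:
    def test_one_fiber_closed_form(self):
        """Uniform tension 30 kPa with Vw/V = 2 gives P = 10 ln 3."""
        V = 50.0e3
        edges = np.linspace(0.0, 2 * V, 25)
        tension = np.full(24, 30.0)
        P = cavity_pressure_from_fiber_tension(tension, V, edges)
        assert P == pytest.approx(10.0 * np.log(3.0), rel=1e-12)

    def test_unloaded_reference_pressure_is_zero(self, model, passive, active):
        assert cavity_pressure(model, model.cavity_volume, None,
                               passive, active) == pytest.approx(0.0, abs=1e-12)

    def test_passive_pv_curve_monotone_convex(self, model, passive, active):
        # monotone from the unloaded volume; convex over the physiologic
        # filling range (just above V0 the tension-only fibre terms switch
        # on layer by layer, which briefly flattens the curvature)
        V = np.linspace(1.0, 1.45, 14) * model.cavity_volume
        P = np.array([cavity_pressure(model, v, None, passive, active)
                      for v in V])
        assert np.all(np.diff(P) > 0)
        V = np.linspace(1.1, 1.45, 12) * model.cavity_volume
        P = np.array([cavity_pressure(model, v, None, passive, active)
                      for v in V])
        assert np.all(np.diff(P, 2) > -1e-9)

    def test_pressure_increases_with_activation(self, model, passive, active):
        V = 1.15 * model.cavity_volume
        p_early = cavity_pressure(model, V, 0.01, passive, active)
        p_peak = cavity_pressure(model, V, active.t0, passive, active)
        p_passive = cavity_pressure(model, V, None, passive, active)
        assert p_peak > p_early > p_passive

    def test_wall_state_consistent_with_pressure(self, model, passive, active):
        V = 1.2 * model.cavity_volume
        ws = lv_pressure_and_stress(model, V, 0.1, passive, active)
        assert ws.pressure == pytest.approx(
            cavity_pressure(model, V, 0.1, passive, active), rel=1e-12)

    def test_radial_stress_spans_minus_p_to_zero(self, model, passive, active):
        V = 1.25 * model.cavity_volume
        ws = lv_pressure_and_stress(model, V, None, passive, active)
        inner = ws.sigma_rr[model.depth < 0.1]
        outer = ws.sigma_rr[model.depth > 0.9]
        assert inner.mean() < outer.mean() <= 1e-9
        assert inner.mean() == pytest.approx(-ws.pressure, rel=0.2)

    def test_mean_stress_mesh_invariant(self, model, passive, active):
        p = model.params
        fine = build_geometry(LVGeometryParams(
            a_endo=p.a_endo, c_endo=p.c_endo, wall_thickness=p.wall_thickness,
            apex_thickness=p.apex_thickness, h_base=p.h_base,
            n_transmural=2 * p.n_transmural,
            n_longitudinal=p.n_longitudinal,
            n_circumferential=p.n_circumferential), seed=1)
        V = 1.2 * model.cavity_volume
        a = lv_pressure_and_stress(model, V, 0.12, passive, active)
        b = lv_pressure_and_stress(fine, V, 0.12, passive, active)
        ma = np.average(a.sigma_f, weights=model.weight)
        mb = np.average(b.sigma_f, weights=fine.weight)
        assert mb == pytest.approx(ma, rel=0.02)
        assert b.pressure == pytest.approx(a.pressure, rel=0.02)
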