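"""Excitations: coil fields, right-hand sides, electrodes, injected current."""

import numpy as np
import pytest

from bemamr import (
    EPS0,
    MU0,
    CoilSpec,
    HeadModel,
    SolverSettings,
    TESVoltageSource,
    TriSurface,
    build_electrode_preconditioner,
    build_nearfield,
    build_rhs,
    injected_current,
    make_icosphere,
    rescale_to_current,
    solve,
    tms_primary_E,
)
from bemamr.operator import ChargeSolution
from bemamr.phantoms import DipoleCluster
from bemamr.sources import EEGSource, UniformFieldSource


def _circular_loop(radius=0.02, n=360, center=(0, 0, 0), normal=(0, 0, 1.0)):
    phi = np.linspace(0, 2 * np.pi, n + 1)
    pts = np.stack(
        [radius * np.cos(phi), radius * np.sin(phi), np.zeros_like(phi)], axis=1
    ) + np.asarray(center)
    seg = np.diff(pts, axis=0)
    lens = np.linalg.norm(seg, axis=1)
    return CoilSpec(0.5 * (pts[:-1] + pts[1:]), seg / lens[:, None], lens)


class TestTMSPrimary:
    def test_zero_didt(self):
        coil = _circular_loop()
        E = tms_primary_E(coil, 0.0, np.array([[0.1, 0.0, 0.05]]))
        assert np.all(E == 0)

    def test_axis_symmetry(self):
        coil = _circular_loop()
        E = tms_primary_E(coil, 9.4e7, np.array([[0.0, 0.0, 0.05]]))
        # azimuthal contributions cancel on the loop axis
        assert np.linalg.norm(E) < 1e-9 * MU0 * 9.4e7 / (4 * np.pi) * 2 * np.pi * 0.02

    def test_far_field_matches_magnetic_dipole(self):
        """Far from a small loop, -dA/dt matches the magnetic-dipole vector
        potential A = mu0/(4 pi) m x r / r^3 with m = I pi a^2."""
        a = 0.005
        coil = _circular_loop(radius=a, n=720)
        didt = 1.0e8
        p = np.array([[0.3, 0.2, 0.4]])
        E = tms_primary_E(coil, didt, p)
        m = np.pi * a**2 * np.array([0, 0, 1.0])  # per unit current
        r = p[0]
        A_dip = MU0 / (4 * np.pi) * np.cross(m, r) / np.linalg.norm(r) ** 3
        np.testing.assert_allclose(E[0], -didt * A_dip, rtol=1e-2)

    def test_segment_coincidence_rejected(self):
        coil = _circular_loop()
        with pytest.raises(ValueError, match="coincides"):
            tms_primary_E(coil, 1.0, coil.midpoints[:1])


class TestBuildRhs:
    def test_zero_contrast_gives_zero_rhs(self):
        model = HeadModel([make_icosphere(0.1, 1)], [0.4], [0.4])
        b = build_rhs(model, UniformFieldSource(np.array([0, 0, 5.0])))
        assert np.all(b == 0)

    def test_uniform_field_cos_theta_pattern(self):
        model = HeadModel([make_icosphere(0.1, 3)], [0.275], [1.654])
        E0 = 3.0
        b = build_rhs(model, UniformFieldSource(np.array([0, 0, E0])))
        K = model.K[0]
        cos_t = model.centroids[:, 2] / np.linalg.norm(model.centroids, axis=1)
        expected = K * EPS0 * E0 * cos_t
        # facet normals deviate from the radial direction at O(edge^2)
        np.testing.assert_allclose(b, expected, atol=1e-2 * np.abs(expected).max())
        assert abs(b.sum()) < 1e-6 * np.abs(b).sum()

    def test_electrode_row_is_v_times_area(self):
        surf = TriSurface(
            np.array([[0, 0, 0], [2e-3, 0, 0], [0, 2e-3, 0.0]]), np.array([[0, 1, 2]])
        )
        model = HeadModel([surf], [0.5], [0.0])
        model.electrodes = {"e": np.array([0])}
        b = build_rhs(model, TESVoltageSource({"e": 1.0}))
        assert b[0] == pytest.approx(model.areas[0], rel=1e-14)
        assert model.areas[0] == pytest.approx(2e-6, rel=1e-12)

    def test_unlabeled_electrode_rejected(self):
        model = HeadModel([make_icosphere(0.1, 1)], [0.5], [0.0])
        model.electrodes = {"e": np.array([0])}
        with pytest.raises(ValueError, match="no electrode labeled"):
            build_rhs(model, TESVoltageSource({"other": 1.0}))


class TestElectrodePreconditioner:
    def test_single_facet_is_scalar_reciprocal(self):
        surf = TriSurface(
            np.array([[0, 0, 0], [1e-3, 0, 0], [0, 1e-3, 0.0]]), np.array([[0, 1, 2]])
        )
        model = HeadModel([surf], [0.5], [0.0])
        model.electrodes = {"e": np.array([0])}
        nf = build_nearfield(model)
        pre = build_electrode_preconditioner(model, nf)
        assert pre.inverse[0, 0] == pytest.approx(1.0 / pre.block[0, 0], rel=1e-12)

    def test_block_times_inverse_is_identity(self):
        model = HeadModel([make_icosphere(0.05, 2)], [0.5], [0.0])
        model.electrodes = {"e": np.arange(0, 40)}
        nf = build_nearfield(model)
        pre = build_electrode_preconditioner(model, nf)
        eye = pre.inverse @ pre.block
        np.testing.assert_allclose(eye, np.eye(40), atol=1e-8)

    def test_electrode_only_problem_converges_immediately(self):
        model = HeadModel([make_icosphere(0.05, 2)], [0.5], [0.0])
        model.electrodes = {"e": np.arange(model.n_facets)}
        nf = build_nearfield(model)
        src = TESVoltageSource({"e": 0.5})
        c, stats = solve(model, src, SolverSettings(), nf, initial=True)
        assert stats.iterations <= 2
        assert stats.final_residual < 1e-5

    def test_guard_threshold(self):
        model = HeadModel([make_icosphere(0.05, 2)], [0.5], [0.0])
        model.electrodes = {"e": np.arange(model.n_facets)}
        nf = build_nearfield(model)
        with pytest.raises(ValueError, match="coarsen"):
            build_electrode_preconditioner(model, nf, guard_threshold=100)


class TestInjectedCurrent:
    @pytest.fixture()
    def charged_sphere(self):
        model = HeadModel([make_icosphere(0.1, 2)], [0.33], [0.0])
        model.electrodes = {"e": np.arange(model.n_facets)}
        nf = build_nearfield(model)
        src = TESVoltageSource({"e": 1.0})
        c, _ = solve(model, src, SolverSettings(), nf, initial=True)
        return model, c, src

    def test_zero_charge_zero_current(self, charged_sphere):
        model, c, src = charged_sphere
        c0 = ChargeSolution(np.zeros_like(c.c), model)
        assert injected_current(model, c0, src, "e") == 0.0

    def test_linearity(self, charged_sphere):
        model, c, src = charged_sphere
        I1 = injected_current(model, c, src, "e")
        c2 = ChargeSolution(2.0 * c.c, model)
        assert injected_current(model, c2, src, "e") == pytest.approx(2 * I1, rel=1e-12)

    def test_capacitance_total_charge(self, charged_sphere):
        """Sphere held at V0: total charge within 2% of 4 pi eps0 R V0."""
        model, c, _ = charged_sphere
        Q_exp = 4 * np.pi * EPS0 * 0.1 * 1.0
        assert c.total_charge == pytest.approx(Q_exp, rel=2e-2)

    def test_rescale_trivial_and_closure(self, charged_sphere):
        model, c, src = charged_sphere
        I = injected_current(model, c, src, "e")
        same = rescale_to_current(c, I, I)
        np.testing.assert_array_equal(same.c, c.c)
        half = rescale_to_current(c, 2e-3, 1e-3)
        np.testing.assert_allclose(half.c, 0.5 * c.c, rtol=1e-15)
        scaled = rescale_to_current(c, I, 1e-3)
        assert injected_current(model, scaled, src, "e") == pytest.approx(
            1e-3, rel=1e-9
        )

    def test_zero_measured_rejected(self, charged_sphere):
        model, c, _ = charged_sphere
        with pytest.raises(ValueError, match="zero"):
            rescale_to_current(c, 0.0, 1e-3)


class TestSolutionNeutrality:
    def test_symmetric_pair_montage_neutral(self):
        """+/-V electrode pair on a symmetric sphere montage: solved total
        charge vanishes within 10x the solver tolerance."""
        model = HeadModel([make_icosphere(0.1, 3)], [0.33], [0.0])
        top = np.flatnonzero(model.centroids[:, 2] > 0.09)
        bot = np.flatnonzero(model.centroids[:, 2] < -0.09)
        model.electrodes = {"plus": top, "minus": bot}
        nf = build_nearfield(model)
        src = TESVoltageSource({"plus": 1.0, "minus": -1.0})
        settings = SolverSettings()
        c, stats = solve(model, src, settings, nf, initial=True)
        assert abs(c.total_charge) <= 10 * settings.gmres_tolerance * np.abs(
            c.Q
        ).sum()

    def test_eeg_cluster_is_neutral_and_solution_nearly_neutral(self):
        cl = DipoleCluster(
            np.array([[0.0, 0, 0.051]]),
            np.array([[0.0, 0, 0.049]]),
            np.array([5e-6]),
        )
        pos, cur = cl.monopoles()
        assert cur.sum() == 0.0
        model = HeadModel([make_icosphere(0.1, 3)], [0.33], [0.0])
        nf = build_nearfield(model)
        settings = SolverSettings()
        c, _ = solve(model, EEGSource(cl), settings, nf, initial=True)
        assert abs(c.total_charge) <= 10 * settings.gmres_tolerance * np.abs(c.Q).sum()
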