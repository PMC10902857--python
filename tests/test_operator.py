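"""Matrix-free operator: backend parity, dense equivalence, field recovery."""

import numpy as np
import pytest

from bemamr import (
    EPS0,
    DirectBackend,
    HeadModel,
    TriSurface,
    apply_R,
    assemble_dense,
    build_nearfield,
    evaluate_E,
    evaluate_V,
    make_icosphere,
    update_nearfield,
)
from bemamr.amr import refine_step
from bemamr.operator import ChargeSolution


class TestBackend:
    def test_compiled_matches_numpy(self, rng):
        src = rng.standard_normal((60, 3))
        q = rng.standard_normal(60)
        tgt = rng.standard_normal((40, 3))
        excl = np.array([[0, 5], [0, 6], [17, 2]])
        fast = DirectBackend(use_compiled=True)
        ref = DirectBackend(use_compiled=False)
        p1, g1 = fast.potential_and_gradient(src, q, tgt, excl)
        p2, g2 = ref.potential_and_gradient(src, q, tgt, excl)
        np.testing.assert_allclose(p1, p2, rtol=1e-12)
        np.testing.assert_allclose(g1, g2, rtol=1e-12)

    def test_coincident_point_contributes_nothing(self):
        src = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        q = np.array([3.0, 2.0])
        pot, _ = DirectBackend().potential_and_gradient(src, q, src[:1])
        assert pot[0] == pytest.approx(2.0 / (4 * np.pi), rel=1e-14)


class TestApplyR:
    def test_zero_charge_maps_to_zero(self, single_shell_model):
        nf = build_nearfield(single_shell_model)
        out = apply_R(single_shell_model, np.zeros(single_shell_model.n_facets), nf)
        assert np.all(out == 0)

    def test_single_isolated_facet_pure_diagonal(self):
        surf = TriSurface(
            np.array([[0, 0, 0], [1e-3, 0, 0], [0, 1e-3, 0.0]]), np.array([[0, 1, 2]])
        )
        model = HeadModel([surf], [1.0], [0.2])
        nf = build_nearfield(model)
        out = apply_R(model, np.array([7.0]), nf)
        assert out[0] == pytest.approx(3.5, rel=1e-14)

    def test_dense_parity_two_shell(self, two_shell_model, rng):
        nf = build_nearfield(two_shell_model)
        R = assemble_dense(two_shell_model, nf)
        x = rng.standard_normal(two_shell_model.n_facets)
        y_free = apply_R(two_shell_model, x, nf)
        y_dense = R @ x
        scale = np.abs(y_dense).max()
        assert np.abs(y_free - y_dense).max() / scale < 1e-10

    def test_dense_parity_with_electrodes(self, two_shell_model, rng):
        m = two_shell_model
        sl = m.surface_slice(1)
        m.electrodes = {"e": np.arange(sl.start, sl.start + 12)}
        nf = build_nearfield(m)
        R = assemble_dense(m, nf)
        x = rng.standard_normal(m.n_facets)
        y_free = apply_R(m, x, nf)
        y_dense = R @ x
        el = m.electrode_indices
        rest = np.setdiff1d(np.arange(m.n_facets), el)
        assert np.abs(y_free[rest] - y_dense[rest]).max() / np.abs(y_dense[rest]).max() < 1e-10
        assert np.abs(y_free[el] - y_dense[el]).max() / np.abs(y_dense[el]).max() < 1e-10

    def test_linearity(self, single_shell_model, rng):
        nf = build_nearfield(single_shell_model)
        x1 = rng.standard_normal(single_shell_model.n_facets)
        x2 = rng.standard_normal(single_shell_model.n_facets)
        a, b = 0.7, -2.3
        lhs = apply_R(single_shell_model, a * x1 + b * x2, nf)
        rhs = a * apply_R(single_shell_model, x1, nf) + b * apply_R(
            single_shell_model, x2, nf
        )
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12, atol=1e-12 * np.abs(rhs).max())

    def test_stale_nearfield_rejected(self, single_shell_model):
        nf = build_nearfield(single_shell_model)
        single_shell_model.subdivide({0: np.array([0])})
        with pytest.raises(ValueError, match="stale near-field"):
            apply_R(single_shell_model, np.zeros(single_shell_model.n_facets), nf)


class TestNearField:
    def test_corrections_decay_with_separation(self):
        """At 20 radii the correction is a tiny fraction of the centroid term."""
        from bemamr.operator import _grad_entries

        a = TriSurface(
            np.array([[0, 0, 0], [0.01, 0, 0], [0, 0.01, 0.0]]), np.array([[0, 1, 2]])
        )
        b = TriSurface(
            np.array([[0.1, 0.1, 0.05], [0.11, 0.1, 0.05], [0.1, 0.11, 0.05]]),
            np.array([[0, 1, 2]]),
        )
        model = HeadModel([a, b], [1, 1], [0, 0])
        corr = _grad_entries(model, np.array([0]), np.array([1]), level=2)[0]
        d = model.centroids[0] - model.centroids[1]
        cent = (
            model.areas[1]
            / (4 * np.pi)
            * np.dot(model.normals[0], d)
            / np.linalg.norm(d) ** 3
        )
        assert abs(corr) <= 1e-3 * abs(cent)

    def test_incremental_update_matches_full_rebuild(self, single_shell_model, rng):
        model = single_shell_model
        nf = build_nearfield(model)
        c = ChargeSolution(rng.standard_normal(model.n_facets), model)
        sel = {0: np.array([0, 7, 100, 211])}
        c2, nf_inc = refine_step(model, c, sel, nf, full_rebuild=False)
        nf_full = build_nearfield(model)
        pairs_inc = {tuple(sorted(p)) for p in nf_inc.pairs.tolist()}
        pairs_full = {tuple(sorted(p)) for p in nf_full.pairs.tolist()}
        assert pairs_inc == pairs_full
        d = (nf_inc.grad_corr - nf_full.grad_corr).tocoo()
        assert np.abs(d.data).max() if d.nnz else 0.0 < 1e-14


class TestFieldRecovery:
    def test_zero_charge_zero_field(self, single_shell_model):
        pts = np.array([[0.0, 0, 0], [0.2, 0, 0]])
        E = evaluate_E(single_shell_model, np.zeros(single_shell_model.n_facets), pts)
        V = evaluate_V(single_shell_model, np.zeros(single_shell_model.n_facets), pts)
        assert np.all(E == 0) and np.all(V == 0)

    def test_gauss_law_uniform_sphere(self, sphere1280):
        """Uniformly charged sphere: E and V outside match the point-charge
        form; E inside vanishes."""
        model = HeadModel(
            [TriSurface(sphere1280.vertices.copy(), sphere1280.facets.copy())],
            [1.0],
            [0.0],
        )
        c0 = 1e-6
        c = np.full(model.n_facets, c0)
        Q = (c * model.areas).sum()
        r_out = np.array([[0.25, 0.0, 0.0], [0.0, -0.3, 0.1]])
        E = evaluate_E(model, c, r_out)
        V = evaluate_V(model, c, r_out)
        for p, Ep, Vp in zip(r_out, E, V):
            r = np.linalg.norm(p)
            assert np.linalg.norm(Ep) == pytest.approx(
                Q / (4 * np.pi * EPS0 * r**2), rel=1e-2
            )
            assert Vp == pytest.approx(Q / (4 * np.pi * EPS0 * r), rel=1e-2)
        E_in = evaluate_E(model, c, np.array([[0.02, 0.01, 0.0]]))
        E_surf = Q / (4 * np.pi * EPS0 * 0.01)
        assert np.linalg.norm(E_in) <= 1e-2 * E_surf

    def test_single_facet_point_charge_limit(self):
        surf = TriSurface(
            np.array([[0, 0, 0], [1e-3, 0, 0], [0, 1e-3, 0.0]]), np.array([[0, 1, 2]])
        )
        model = HeadModel([surf], [1.0], [0.0])
        c = np.array([2.0e-6])
        q = c[0] * model.areas[0]
        p = np.array([[0.1, 0.05, 0.08]])
        E = evaluate_E(model, c, p)
        d = p[0] - model.centroids[0]
        E_pc = q * d / (4 * np.pi * EPS0 * np.linalg.norm(d) ** 3)
        np.testing.assert_allclose(E[0], E_pc, rtol=1e-4)

    def test_centroid_coincidence_rejected_for_E(self, single_shell_model):
        p = single_shell_model.centroids[:1]
        with pytest.raises(ValueError, match="coincides"):
            evaluate_E(single_shell_model, np.ones(single_shell_model.n_facets), p)

    def test_potential_allowed_on_surface(self, single_shell_model):
        p = single_shell_model.centroids[:3]
        V = evaluate_V(single_shell_model, np.ones(single_shell_model.n_facets), p)
        assert np.all(np.isfinite(V))

    def test_potential_consistent_with_field_line_integral(self, sphere1280, rng):
        """V(a) - V(b) equals the line integral of E along a path (coarse
        quadrature)."""
        model = HeadModel(
            [TriSurface(sphere1280.vertices.copy(), sphere1280.facets.copy())],
            [1.0],
            [0.0],
        )
        c = 1e-6 * (1.0 + 0.3 * model.centroids[:, 2] / 0.1)
        a = np.array([0.15, 0.02, 0.0])
        b = np.array([0.3, -0.05, 0.1])
        V = evaluate_V(model, c, np.stack([a, b]))
        ts = np.linspace(0, 1, 200)
        path = a[None, :] + ts[:, None] * (b - a)[None, :]
        E = evaluate_E(model, c, path)
        integrand = E @ (b - a)
        line = np.trapezoid(integrand, ts)
        assert (V[0] - V[1]) == pytest.approx(line, rel=1e-2)
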