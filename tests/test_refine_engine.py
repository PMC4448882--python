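"""Normal-equations accumulation, preconditioning, solvers and refinement."""

import numpy as np
import pytest

import microrefine as mr
from microrefine.refine_engine import _ldlt_solve


def _spd(n, seed):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n, n))
    return a @ a.T + n * np.eye(n)


class TestAccumulation:
    def test_single_reflection_rank_one(self, recovery_problem):
        truth, data, _, constraints = recovery_problem
        pmap = mr.build_parameter_map(truth.copy(), constraints)
        one = mr.ReflectionSet(hkl=data.hkl[:1], y=data.y[:1], sigma=data.sigma[:1])
        ne = mr.accumulate_normal_matrix(truth, one, pmap)
        row = mr.design_row(truth, data.hkl[0], pmap)
        w = 1.0 / data.sigma[0] ** 2
        assert np.allclose(ne.N, w * np.outer(row, row), rtol=1e-10)

    def test_batch_size_invariance(self, recovery_problem):
        truth, data, _, constraints = recovery_problem
        pmap = mr.build_parameter_map(truth.copy(), constraints)
        sub = mr.ReflectionSet(hkl=data.hkl[:300], y=data.y[:300], sigma=data.sigma[:300])
        ne1 = mr.accumulate_normal_matrix(truth, sub, pmap, batch_size=1)
        ne64 = mr.accumulate_normal_matrix(truth, sub, pmap, batch_size=64)
        scale = np.abs(ne1.N).max()
        assert np.abs(ne1.N - ne64.N).max() / scale < 1e-10
        assert np.allclose(ne1.g, ne64.g, rtol=1e-10, atol=1e-10 * scale)

    def test_matches_dense_design_product_oracle(self, recovery_problem):
        """N from batched accumulation equals the naive Bᵗ W B product."""
        truth, data, _, constraints = recovery_problem
        pmap = mr.build_parameter_map(truth.copy(), constraints)
        sub = mr.ReflectionSet(hkl=data.hkl[:200], y=data.y[:200], sigma=data.sigma[:200])
        ne = mr.accumulate_normal_matrix(truth, sub, pmap, batch_size=32)
        B = np.vstack([mr.design_row(truth, h, pmap) for h in sub.hkl])
        w = 1.0 / sub.sigma**2
        oracle = (B * w[:, None]).T @ B
        assert np.allclose(ne.N, oracle, rtol=1e-8)

    def test_no_free_parameters_rejected(self, cubic_cell):
        model = mr.CrystalModel(
            cell=cubic_cell, scale_fixed=True,
            atoms=[mr.AtomSite(label="C1", element="C", frac=np.zeros(3), u_iso=0.02,
                               fix=frozenset({"x", "y", "z", "uiso"}))],
        )
        with pytest.raises(mr.NothingToRefineError):
            mr.build_parameter_map(model)


class TestRestraintAccumulation:
    def test_distance_row_touches_6x6_block(self, pyridine):
        model = pyridine.model
        pmap = mr.build_parameter_map(model)
        n = pmap.n_free
        ne = mr.NormalEquations(N=np.zeros((n, n)), g=np.zeros(n))
        r = mr.Restraint("DISTANCE", atoms=("C2", "C3"), target=1.39, sigma=0.01)
        row = mr.restraint_equation(r, model, pmap)
        mr.accumulate_restraints(ne, [row])
        touched = np.argwhere(ne.N != 0)
        involved = sorted({i for pair in touched for i in pair})
        assert len(involved) <= 6

    def test_empty_set_leaves_n_unchanged(self):
        ne = mr.NormalEquations(N=_spd(5, 0), g=np.zeros(5))
        before = ne.N.copy()
        mr.accumulate_restraints(ne, [])
        assert np.array_equal(ne.N, before)

    def test_sparse_equals_dense_outer_products(self):
        rng = np.random.default_rng(9)
        n = 30
        rows = []
        dense = np.zeros((n, n))
        gref = np.zeros(n)
        for _ in range(50):
            idx = rng.choice(n, size=rng.integers(1, 7), replace=False)
            vals = rng.standard_normal(idx.size)
            res = rng.standard_normal()
            full = np.zeros(n)
            full[idx] = vals
            dense += np.outer(full, full)
            gref -= full * res
            rows.append((res, dict(zip(map(int, idx), vals))))
        ne = mr.NormalEquations(N=np.zeros((n, n)), g=np.zeros(n))
        mr.accumulate_restraints(ne, rows)
        assert np.allclose(ne.N, dense, atol=1e-12)
        assert np.allclose(ne.g, gref, atol=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(10)
        n = 20
        rows = []
        for _ in range(40):
            idx = rng.choice(n, size=4, replace=False)
            rows.append((rng.standard_normal(),
                         dict(zip(map(int, idx), rng.standard_normal(4)))))
        ne1 = mr.NormalEquations(N=np.zeros((n, n)), g=np.zeros(n))
        mr.accumulate_restraints(ne1, rows)
        ne2 = mr.NormalEquations(N=np.zeros((n, n)), g=np.zeros(n))
        mr.accumulate_restraints(ne2, rows[::-1])
        assert np.abs(ne1.N - ne2.N).max() < 1e-10 * max(np.abs(ne1.N).max(), 1.0)

    def test_out_of_range_index_rejected(self):
        ne = mr.NormalEquations(N=np.zeros((3, 3)), g=np.zeros(3))
        with pytest.raises(IndexError):
            mr.accumulate_restraints(ne, [(0.0, {5: 1.0})])


class TestPreconditioning:
    def test_identity_unchanged(self):
        ne = mr.NormalEquations(N=np.eye(4), g=np.zeros(4))
        np_, c = mr.precondition(ne)
        assert np.allclose(c, 1.0)
        assert np.allclose(np_, np.eye(4))

    def test_diagonal_closed_form(self):
        ne = mr.NormalEquations(N=np.diag([4.0, 25.0]), g=np.zeros(2))
        np_, c = mr.precondition(ne)
        assert np.allclose(c, [0.5, 0.2])
        assert np.allclose(np_, np.eye(2))

    def test_unit_diagonal_and_inverse_recovery(self):
        """Seeded SPD system: unit diagonal to 1e-12; C N'⁻¹ C = N⁻¹ to 1e-8."""
        n = 40
        N = _spd(n, 1234)
        # wildly different parameter scales to make conditioning matter
        s = np.logspace(-3, 3, n)
        N = s[:, None] * N * s[None, :]
        ne = mr.NormalEquations(N=N, g=np.zeros(n))
        np_, c = mr.precondition(ne)
        assert np.abs(np.diag(np_) - 1.0).max() < 1e-12
        recovered = (c[:, None] * np.linalg.inv(np_)) * c[None, :]
        direct = np.linalg.inv(N)
        assert np.allclose(recovered, direct, rtol=1e-8)

    def test_zero_diagonal_flagged_undetermined(self):
        N = np.diag([1.0, 0.0, 2.0])
        ne = mr.NormalEquations(N=N, g=np.zeros(3))
        np_, c = mr.precondition(ne)
        assert ne.undetermined == (1,)
        assert c[1] == 0.0

    def test_all_zero_diagonal_rejected(self):
        ne = mr.NormalEquations(N=np.zeros((3, 3)), g=np.zeros(3))
        with pytest.raises(mr.NothingToRefineError):
            mr.precondition(ne)

    def test_eq3_identity_on_solve(self, recovery_problem):
        """C N'⁻¹ C · N ≈ I on a well-conditioned refinement system."""
        truth, data, _, constraints = recovery_problem
        pmap = mr.build_parameter_map(truth.copy(), constraints)
        ne = mr.accumulate_normal_matrix(truth, data, pmap)
        np_, c = mr.precondition(ne)
        _, ninv_p = mr.solve_normal_equations(np_, c * ne.g)
        n_inv = (c[:, None] * ninv_p) * c[None, :]
        assert np.allclose(n_inv @ ne.N, np.eye(pmap.n_free), atol=1e-6)


class TestSolvers:
    def test_identity_system(self):
        b = np.array([1.0, -2.0, 3.0])
        x, _ = mr.solve_normal_equations(np.eye(3), b)
        assert np.allclose(x, b)

    def test_ldlt_matches_dense_inverse_oracle(self):
        N = _spd(25, 77)
        g = np.random.default_rng(78).standard_normal(25)
        x, ninv = mr.solve_normal_equations(N, g, method="ldlt")
        assert np.allclose(x, np.linalg.inv(N) @ g, rtol=1e-8)
        assert np.allclose(ninv, np.linalg.inv(N), rtol=1e-8)

    def test_indefinite_system_solved(self):
        """Bunch-Kaufman handles symmetric-indefinite matrices."""
        N = np.array([[0.0, 1.0], [1.0, 0.0]])
        x, _ = _ldlt_solve(N, np.array([2.0, 3.0]))
        assert np.allclose(x, [3.0, 2.0])

    def _rank_deficient_system(self):
        # two perfectly collinear parameters
        a = np.random.default_rng(5).standard_normal((10, 3))
        B = np.column_stack([a[:, 0], a[:, 1], a[:, 0] + a[:, 1]])
        return B.T @ B, B.T @ np.ones(10)

    def test_ldlt_raises_on_singular_with_parameter_names(self):
        N, g = self._rank_deficient_system()
        with pytest.raises(mr.SingularMatrixError) as exc:
            mr.solve_normal_equations(N, g, method="ldlt", names=["p0", "p1", "p2"])
        assert exc.value.parameter_names

    def test_eigen_filter_returns_finite_shifts_with_null_direction_unshifted(self):
        N, g = self._rank_deficient_system()
        x, _ = mr.solve_normal_equations(N, g, method="eigen_filter", filter_tol=1e-8)
        assert np.all(np.isfinite(x))
        null = np.array([1.0, 1.0, -1.0]) / np.sqrt(3)  # exact null space of N
        assert abs(null @ x) < 1e-8

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            mr.solve_normal_equations(np.array([[1.0, 2.0], [0.0, 1.0]]), np.ones(2))


class TestConditionDiagnostics:
    def test_identity_has_condition_one(self):
        diag = mr.condition_diagnostics(np.eye(5))
        assert diag["condition_number"] == pytest.approx(1.0)

    def test_diagonal_condition_number(self):
        diag = mr.condition_diagnostics(np.diag([100.0, 1.0]))
        assert diag["condition_number"] == pytest.approx(100.0)

    def test_collinear_occupancies_dominate_smallest_eigenvector(self):
        """Two same-site scatterers with free occupancies: the flat direction
        is the occupancy transfer between them."""
        fx = mr.make_fixture("collinear_occupancy")
        model = fx.model
        data = mr.simulate_observations(model, d_min=1.0, noise_frac=0.02, seed=5)
        pmap = mr.build_parameter_map(model, [mr.Fix("C1", ("x", "y", "z"))])
        ne = mr.accumulate_normal_matrix(model, data, pmap)
        np_, _ = mr.precondition(ne)
        diag = mr.condition_diagnostics(np_, names=pmap.names)
        top2 = set(diag["modes"][0]["labels"][:2])
        assert top2 == {"NI1.occ", "NI2.occ"}

    def test_occupancy_sum_constraint_improves_conditioning_10x(self):
        fx = mr.make_fixture("collinear_occupancy")
        model = fx.model
        data = mr.simulate_observations(model, d_min=1.0, noise_frac=0.02, seed=5)

        def cond(constraints):
            pmap = mr.build_parameter_map(model.copy(), constraints)
            ne = mr.accumulate_normal_matrix(model, data, pmap)
            np_, _ = mr.precondition(ne)
            return mr.condition_diagnostics(np_)["condition_number"]

        base = [mr.Fix("C1", ("x", "y", "z"))]
        free = cond(base)
        constrained = cond(base + [mr.OccupancySum(("NI1", "NI2"), 1.0)])
        assert free / constrained >= 10.0


class TestRefine:
    def test_zero_cycles_returns_unchanged_model_with_statistics(self, recovery_problem):
        truth, data, pert, constraints = recovery_problem
        pmap = mr.build_parameter_map(pert, constraints)
        res = mr.refine(pert, data, pmap, config=mr.RefineConfig(max_cycles=0))
        assert len(res.history) == 1
        assert res.history[0]["R1"] > 0
        for atom in pert.atoms:
            assert np.allclose(res.model.get_site(atom.label).frac, atom.frac)

    def test_noiseless_recovery(self, recovery_problem):
        """Exact data, 0.02-fractional perturbation: R1 < 1e-6 and coordinates
        recovered to 1e-5."""
        truth, data, pert, constraints = recovery_problem
        pmap = mr.build_parameter_map(pert, constraints)
        res = mr.refine(pert, data, pmap, config=mr.RefineConfig(max_cycles=20, tol=1e-3))
        assert res.converged
        assert res.final["R1"] < 1e-6
        for atom in truth.atoms:
            assert np.abs(res.model.get_site(atom.label).frac - atom.frac).max() < 1e-5

    def test_objective_monotone_on_noiseless_fixture(self, recovery_problem):
        truth, data, pert, constraints = recovery_problem
        pmap = mr.build_parameter_map(pert, constraints)
        res = mr.refine(pert, data, pmap, config=mr.RefineConfig(max_cycles=12, tol=1e-3))
        m_values = [h["M"] for h in res.history]
        assert all(b <= a * (1 + 1e-12) for a, b in zip(m_values, m_values[1:]))

    def test_noisy_recovery_within_esds(self):
        """2 % noise, 20 seeds: ≥95 % of parameters within 3 esd of truth."""
        total = within = 0
        truth = mr.make_fixture("random_structure", seed=1).model
        for seed in range(20):
            data = mr.simulate_observations(truth, d_min=0.9, noise_frac=0.02, seed=100 + seed)
            pert = truth.copy()
            rng = np.random.default_rng(200 + seed)
            for atom in pert.atoms[1:]:
                atom.frac = atom.frac + rng.uniform(-0.02, 0.02, 3)
            pmap = mr.build_parameter_map(pert, [mr.Fix(truth.atoms[0].label, ("x", "y", "z"))])
            res = mr.refine(pert, data, pmap,
                            config=mr.RefineConfig(max_cycles=15, tol=0.005))
            v_truth = pmap.gather(truth)
            v_fit = pmap.gather(res.model)
            esd = np.array([res.esds[name] for name in pmap.names])
            ok = np.abs(v_fit - v_truth) <= 3 * esd
            total += ok.size
            within += int(ok.sum())
        assert within / total >= 0.95

    def test_underdetermined_warns(self, cubic_cell):
        model = mr.CrystalModel(
            cell=cubic_cell,
            atoms=[mr.AtomSite(label="C1", element="C", frac=np.array([0.1, 0.2, 0.3]),
                               u_iso=0.02)],
        )
        data = mr.ReflectionSet(hkl=np.array([[1, 0, 0], [0, 1, 0]]),
                                y=np.array([1.0, 1.0]), sigma=np.array([0.1, 0.1]))
        pmap = mr.build_parameter_map(model)
        with pytest.warns(UserWarning):
            mr.refine(model, data, pmap, config=mr.RefineConfig(max_cycles=0))
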