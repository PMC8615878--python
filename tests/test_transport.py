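"""Optimal transport: measures, cost, Sinkhorn, group penalty, barycenter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from errpot.transport import (CostMatrix, OTConfig, barycentric_map,
                              cost_matrix, empirical_measure, exact_ot_oracle,
                              group_lasso_transport, sinkhorn, TransportPlan)


def _purity(tau, labels):
    mc = tau[labels == "correct"].sum(axis=0)
    mi = tau[labels == "incorrect"].sum(axis=0)
    return float(np.mean(np.maximum(mc, mi) / (mc + mi)))


def _two_cluster_instance(rng, n_src=20, n_tgt=14):
    """Class-pure, well-separated clusters in 2-D."""
    Xs = np.vstack([rng.normal(size=(n_src, 2)),
                    rng.normal(size=(n_src, 2)) + 6.0])
    ys = np.array(["correct"] * n_src + ["incorrect"] * n_src)
    Xt = np.vstack([rng.normal(size=(n_tgt, 2)) + 0.5,
                    rng.normal(size=(n_tgt, 2)) + 6.5])
    yt = np.array(["correct"] * n_tgt + ["incorrect"] * n_tgt)
    ms, mt = empirical_measure(Xs), empirical_measure(Xt)
    J = cost_matrix(ms, mt)
    J = CostMatrix(J.values / np.median(J.values))
    return J, ms, mt, ys, yt


class TestEmpiricalMeasure:
    def test_uniform_mass(self, rng):
        m = empirical_measure(rng.normal(size=(4, 3)))
        np.testing.assert_allclose(m.mass, 0.25)
        assert abs(m.mass.sum() - 1.0) < 1e-12

    def test_single_point(self):
        m = empirical_measure(np.array([[1.0, 2.0]]))
        np.testing.assert_allclose(m.mass, [1.0])

    def test_weight_renormalization(self, rng):
        m = empirical_measure(rng.normal(size=(3, 2)),
                              weights=np.array([2.0, 2.0, 4.0]))
        np.testing.assert_allclose(m.mass, [0.25, 0.25, 0.5])

    def test_zero_or_negative_weights_rejected(self, rng):
        pts = rng.normal(size=(3, 2))
        with pytest.raises(ValueError):
            empirical_measure(pts, weights=np.zeros(3))
        with pytest.raises(ValueError):
            empirical_measure(pts, weights=np.array([1.0, -1.0, 1.0]))


class TestCostMatrix:
    def test_three_four_five(self):
        ms = empirical_measure(np.array([[0.0, 0.0]]))
        mt = empirical_measure(np.array([[3.0, 4.0]]))
        assert cost_matrix(ms, mt).values[0, 0] == pytest.approx(25.0)

    def test_identical_supports_zero_diagonal(self, rng):
        pts = rng.normal(size=(5, 4))
        J = cost_matrix(empirical_measure(pts), empirical_measure(pts))
        np.testing.assert_allclose(np.diag(J.values), 0.0, atol=1e-12)

    def test_matches_double_loop_reference(self, rng):
        A = rng.normal(size=(5, 3))
        B = rng.normal(size=(6, 3))
        J = cost_matrix(empirical_measure(A), empirical_measure(B)).values
        ref = np.array([[np.sum((a - b) ** 2) for b in B] for a in A])
        np.testing.assert_allclose(J, ref, atol=1e-10)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="dimension"):
            cost_matrix(empirical_measure(rng.normal(size=(3, 2))),
                        empirical_measure(rng.normal(size=(3, 4))))


class TestSinkhorn:
    def test_one_by_one_forced_coupling(self):
        plan = sinkhorn(CostMatrix(np.array([[2.0]])), np.array([1.0]),
                        np.array([1.0]), 0.5)
        np.testing.assert_allclose(plan.coupling, [[1.0]], atol=1e-12)

    def test_two_by_two_matches_lp_vertex(self):
        J = CostMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        u = np.array([0.5, 0.5])
        plan = sinkhorn(J, u, u, 0.01)
        np.testing.assert_allclose(plan.coupling,
                                   [[0.5, 0.0], [0.0, 0.5]], atol=1e-3)

    def test_symmetric_instance_gives_symmetric_plan(self, rng):
        A = rng.normal(size=(3, 3))
        J = CostMatrix((A + A.T) / 2 + 1.0 - np.min(A))
        u = np.full(3, 1 / 3)
        plan = sinkhorn(J, u, u, 0.5)
        np.testing.assert_allclose(plan.coupling, plan.coupling.T, atol=1e-8)

    def test_marginals_and_nonnegativity(self, rng):
        for _ in range(5):
            ns, nt = rng.integers(2, 7, size=2)
            J = CostMatrix(rng.random((ns, nt)))
            ps = empirical_measure(rng.normal(size=(ns, 1)),
                                   rng.random(ns) + 0.1).mass
            pt = empirical_measure(rng.normal(size=(nt, 1)),
                                   rng.random(nt) + 0.1).mass
            plan = sinkhorn(J, ps, pt, 0.1)
            assert np.all(plan.coupling >= 0)
            np.testing.assert_allclose(plan.coupling.sum(1), ps, atol=1e-9)
            np.testing.assert_allclose(plan.coupling.sum(0), pt, atol=1e-9)

    def test_objective_trace_recorded(self, rng):
        J = CostMatrix(rng.random((4, 4)))
        u = np.full(4, 0.25)
        plan = sinkhorn(J, u, u, 0.5)
        assert len(plan.objective_trace) >= 1

    def test_nonpositive_lambda_rejected(self):
        J = CostMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        u = np.array([0.5, 0.5])
        with pytest.raises(ValueError):
            sinkhorn(J, u, u, 0.0)

    def test_plain_scaling_underflow_advises_log_domain(self):
        # every kernel entry underflows to zero in plain scaling
        J = CostMatrix(np.array([[500.0, 1000.0], [1000.0, 500.0]]))
        u = np.array([0.5, 0.5])
        with pytest.raises(FloatingPointError, match="log_domain"):
            sinkhorn(J, u, u, 0.1, log_domain=False)
        # the log-domain path solves the same instance
        plan = sinkhorn(J, u, u, 0.1, log_domain=True)
        np.testing.assert_allclose(plan.coupling,
                                   [[0.5, 0.0], [0.0, 0.5]], atol=1e-6)


class TestGroupLassoTransport:
    def test_eta_zero_reduces_to_sinkhorn(self, rng):
        J, ms, mt, ys, _ = _two_cluster_instance(rng)
        cfg = OTConfig(eta_group=0.0, label_mode="unsupervised_target")
        plan = group_lasso_transport(J, ms.mass, mt.mass, ys, None, cfg)
        ref = sinkhorn(J, ms.mass, mt.mass, cfg.lambda_entropy)
        np.testing.assert_allclose(plan.coupling, ref.coupling, atol=1e-9)

    def test_paper_eta_gives_class_pure_columns(self, rng):
        # eta = 10 on class-pure clusters: >= 99% of each column's mass
        # must come from a single source class
        J, ms, mt, ys, _ = _two_cluster_instance(rng)
        cfg = OTConfig(eta_group=10.0, label_mode="unsupervised_target")
        plan = group_lasso_transport(J, ms.mass, mt.mass, ys, None, cfg)
        mc = plan.coupling[ys == "correct"].sum(axis=0)
        mi = plan.coupling[ys == "incorrect"].sum(axis=0)
        col_purity = np.maximum(mc, mi) / (mc + mi)
        assert np.all(col_purity >= 0.99)

    def test_purity_nondecreasing_in_eta(self, rng):
        J, ms, mt, ys, _ = _two_cluster_instance(rng)
        purities = []
        for eta in (0.0, 0.1, 1.0, 10.0):
            cfg = OTConfig(eta_group=eta, label_mode="unsupervised_target")
            plan = group_lasso_transport(J, ms.mass, mt.mass, ys, None, cfg)
            purities.append(_purity(plan.coupling, ys))
        assert all(a <= b + 1e-9 for a, b in zip(purities, purities[1:]))

    def test_semisupervised_mask_respects_target_labels(self, rng):
        J, ms, mt, ys, yt = _two_cluster_instance(rng)
        plan = group_lasso_transport(J, ms.mass, mt.mass, ys, yt, OTConfig())
        cross = plan.coupling[np.ix_(ys == "correct", yt == "incorrect")]
        assert cross.sum() < 1e-6

    def test_semisupervised_requires_target_labels(self, rng):
        J, ms, mt, ys, _ = _two_cluster_instance(rng)
        with pytest.raises(ValueError, match="target labels"):
            group_lasso_transport(J, ms.mass, mt.mass, ys, None, OTConfig())

    def test_unknown_labels_rejected(self, rng):
        J, ms, mt, ys, _ = _two_cluster_instance(rng)
        bad = ys.copy()
        bad[0] = "maybe"
        cfg = OTConfig(label_mode="unsupervised_target")
        with pytest.raises(ValueError, match="unknown"):
            group_lasso_transport(J, ms.mass, mt.mass, bad, None, cfg)

    def test_permutation_equivariance(self, rng):
        J, ms, mt, ys, _ = _two_cluster_instance(rng)
        cfg = OTConfig(label_mode="unsupervised_target")
        plan = group_lasso_transport(J, ms.mass, mt.mass, ys, None, cfg)
        perm = rng.permutation(len(ys))
        plan_p = group_lasso_transport(CostMatrix(J.values[perm]), ms.mass,
                                       mt.mass, ys[perm], None, cfg)
        np.testing.assert_allclose(plan.coupling[perm], plan_p.coupling,
                                   atol=1e-10)

    def test_marginal_conservation_on_returned_plans(self, rng):
        J, ms, mt, ys, yt = _two_cluster_instance(rng)
        for cfg in (OTConfig(label_mode="unsupervised_target"),
                    OTConfig()):
            tl = yt if cfg.label_mode == "semisupervised_target" else None
            plan = group_lasso_transport(J, ms.mass, mt.mass, ys, tl, cfg)
            assert plan.marginal_error <= 1e-9
            assert np.all(plan.coupling >= 0)


class TestBarycentricMap:
    def test_identity_coupling_moves_source_onto_target(self, rng):
        pts = rng.normal(size=(4, 3))
        target = empirical_measure(pts)
        plan = TransportPlan(coupling=np.diag(target.mass),
                             source_mass=target.mass, target_mass=target.mass)
        mapped = barycentric_map(plan, target)
        np.testing.assert_allclose(mapped.points, pts, atol=1e-12)

    def test_hand_computed_weighted_average(self):
        target = empirical_measure(np.array([[0.0], [10.0]]))
        plan = TransportPlan(coupling=np.array([[0.3, 0.2], [0.1, 0.4]]),
                             source_mass=np.array([0.5, 0.5]),
                             target_mass=np.array([0.4, 0.6]))
        mapped = barycentric_map(plan, target)
        np.testing.assert_allclose(mapped.points, [[4.0], [8.0]])

    def test_outputs_in_target_convex_hull(self, rng):
        for _ in range(5):
            Xs = rng.normal(size=(6, 3))
            Xt = rng.normal(size=(5, 3))
            ms, mt = empirical_measure(Xs), empirical_measure(Xt)
            plan = sinkhorn(cost_matrix(ms, mt), ms.mass, mt.mass, 1.0)
            mapped = barycentric_map(plan, mt).points
            assert np.all(mapped >= Xt.min(axis=0) - 1e-9)
            assert np.all(mapped <= Xt.max(axis=0) + 1e-9)

    def test_zero_row_mass_errors_with_index(self):
        target = empirical_measure(np.array([[0.0], [1.0]]))
        plan = TransportPlan(coupling=np.array([[0.0, 0.0], [0.5, 0.5]]),
                             source_mass=np.array([0.0, 1.0]),
                             target_mass=np.array([0.5, 0.5]))
        with pytest.raises(ValueError, match="index 0"):
            barycentric_map(plan, target)


class TestExactOracle:
    def test_perfect_matching_zero_objective(self):
        J = CostMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        u = np.array([0.5, 0.5])
        plan = exact_ot_oracle(J, u, u)
        assert plan.transport_cost(J) == pytest.approx(0.0, abs=1e-12)

    def test_lp_lower_bounds_sinkhorn_cost(self, rng):
        for _ in range(5):
            J = CostMatrix(rng.random((3, 3)))
            u = np.full(3, 1 / 3)
            oracle = exact_ot_oracle(J, u, u)
            for lam in (0.05, 0.5, 5.0):
                plan = sinkhorn(J, u, u, lam)
                assert (oracle.transport_cost(J)
                        <= plan.transport_cost(J) + 1e-9)

    def test_sinkhorn_approaches_lp_at_small_lambda(self, rng):
        for _ in range(3):
            X = rng.normal(size=(4, 2))
            Y = rng.normal(size=(4, 2))
            ms, mt = empirical_measure(X), empirical_measure(Y)
            J = cost_matrix(ms, mt)
            oracle = exact_ot_oracle(J, ms.mass, mt.mass)
            lam = 1e-3 * np.median(J.values)
            plan = sinkhorn(J, ms.mass, mt.mass, lam, max_iter=20_000,
                            tol=1e-12)
            rel = (abs(plan.transport_cost(J) - oracle.transport_cost(J))
                   / oracle.transport_cost(J))
            assert rel < 0.01

    def test_size_limit(self, rng):
        J = CostMatrix(rng.random((25, 25)))
        u = np.full(25, 1 / 25)
        with pytest.raises(ValueError, match="400"):
            exact_ot_oracle(J, u, u)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=2, max_value=6), st.integers(min_value=2, max_value=6),
       st.integers(min_value=0, max_value=10_000))
def test_sinkhorn_plan_is_a_valid_coupling(ns, nt, seed):
    """Property: any Sinkhorn plan is nonnegative with exact marginals."""
    rng = np.random.default_rng(seed)
    J = CostMatrix(rng.random((ns, nt)) * 5.0)
    ps = rng.random(ns) + 0.05
    ps /= ps.sum()
    pt = rng.random(nt) + 0.05
    pt /= pt.sum()
    plan = sinkhorn(J, ps, pt, 0.2)
    assert np.all(plan.coupling >= 0)
    np.testing.assert_allclose(plan.coupling.sum(1), ps, atol=1e-9)
    np.testing.assert_allclose(plan.coupling.sum(0), pt, atol=1e-9)
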