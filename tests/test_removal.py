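import numpy as np
import pytest

from sessilecmr import (
    depletion_pairs,
    leslie_fit,
    mln,
    permutation_removal,
    simulate_population,
    single_plot_config,
)

from conftest import make_dataset


class TestDepletionPairs:
    def test_hand_enumerated_example(self):
        # occasion 1 detects {a,b}, occasion 2 detects {b,c}
        D = np.array([[1, 0], [1, 1], [0, 1]])
        assert depletion_pairs(D, [0, 1]) == [(0, 2), (2, 1)]

    def test_identical_occasions(self):
        D = np.tile(np.array([[1], [1], [1]]), (1, 3))
        assert depletion_pairs(D, [0, 1, 2]) == [(0, 3), (3, 0), (3, 0)]

    def test_structure_invariants(self, rng):
        D = (rng.random((20, 6)) < 0.4).astype(int)
        pairs = depletion_pairs(D, rng.permutation(6))
        xs, ys = zip(*pairs)
        assert xs[0] == 0
        assert all(xs[t + 1] == xs[t] + ys[t] for t in range(5))
        assert sum(ys) == int((D.sum(axis=1) >= 1).sum())

    def test_bad_order_rejected(self):
        with pytest.raises(ValueError, match="permutation"):
            depletion_pairs(np.ones((2, 3), dtype=int), [0, 1, 1])

    def test_geometric_decline_expectation(self):
        # E[y_t] = N p (1-p)^(t-1), E[x_t] = N (1 - (1-p)^(t-1)) at p=0.5;
        # averaged over 500 simulated datasets.
        N, p, T, n_rep = 100, 0.5, 5, 500
        ys = np.zeros(T)
        xs = np.zeros(T)
        for s in range(n_rep):
            ds = simulate_population(single_plot_config(N, p, n_occasions=T, seed=s))
            m = ds.matrix("P")
            full = np.zeros((N, T), dtype=np.int8)
            full[: m.shape[0]] = m  # undetected rows are all-zero anyway
            pairs = depletion_pairs(full, np.arange(T))
            xs += [pr[0] for pr in pairs]
            ys += [pr[1] for pr in pairs]
        t = np.arange(T)
        np.testing.assert_allclose(ys / n_rep, N * p * (1 - p) ** t, rtol=0.05)
        np.testing.assert_allclose(
            (xs / n_rep)[1:], (N * (1 - (1 - p) ** t))[1:], rtol=0.05
        )


class TestLeslieFit:
    def test_exact_geometric_points(self):
        # y = p(N - x) with N=100, p=0.5: points are exactly collinear.
        pairs = [(0.0, 50.0), (50.0, 25.0), (75.0, 12.5), (87.5, 6.25)]
        f = leslie_fit(pairs)
        assert not f.degenerate
        assert f.slope == pytest.approx(-0.5, abs=1e-12)
        assert f.x_intercept == pytest.approx(100.0, abs=1e-9)

    def test_non_declining_fit_is_degenerate(self):
        f = leslie_fit([(0, 1), (1, 2), (3, 5)])
        assert f.degenerate and f.x_intercept is None

    def test_constant_x_is_degenerate(self):
        f = leslie_fit([(3, 1), (3, 2)])
        assert f.degenerate

    def test_matches_normal_equations_oracle(self, rng):
        import statsmodels.api as sm

        for _ in range(100):
            n = rng.integers(3, 10)
            x = rng.random(n) * 50
            y = rng.random(n) * 20
            f = leslie_fit(list(zip(x, y)))
            ref = sm.OLS(y, sm.add_constant(x)).fit()
            assert f.intercept == pytest.approx(ref.params[0], abs=1e-10)
            assert f.slope == pytest.approx(ref.params[1], abs=1e-10)


class TestPermutationRemoval:
    def test_perfect_first_occasion(self):
        # every surveyor detects everything: all permutations give N = MLN
        D = np.ones((12, 4), dtype=int)
        est = permutation_removal(D, n_perm=500, seed=0)
        assert est.point_estimate == pytest.approx(12.0)
        assert est.ci95 == (pytest.approx(12.0), pytest.approx(12.0))
        assert est.n_degenerate == 0

    def test_two_occasion_single_permutation_symmetric_lincoln_petersen(self, rng):
        # with n1 = n2 the 2-point regression x-intercept equals n1*n2/m2
        for _ in range(50):
            while True:
                D = (rng.random((30, 2)) < 0.4).astype(int)
                D = D[D.sum(axis=1) > 0]
                n1, n2 = D.sum(axis=0)
                m2 = int((D.sum(axis=1) == 2).sum())
                if n1 == n2 and 0 < m2 < n2:
                    break
            f = leslie_fit(depletion_pairs(D, [0, 1]))
            assert f.x_intercept == pytest.approx(n1 * n2 / m2, rel=1e-12)

    def test_invariant_to_row_order(self, rng):
        D = (rng.random((25, 6)) < 0.3).astype(int)
        D = D[D.sum(axis=1) > 0]
        a = permutation_removal(D, n_perm=800, seed=11)
        b = permutation_removal(D[::-1], n_perm=800, seed=11)
        assert a.point_estimate == pytest.approx(b.point_estimate)
        assert a.ci95 == pytest.approx(b.ci95)

    def test_uninformative_occasion_does_not_inflate_median(self, rng):
        D = (rng.random((25, 6)) < 0.35).astype(int)
        D = D[D.sum(axis=1) > 0]
        base = permutation_removal(D, n_perm=3000, seed=4)
        padded = np.column_stack([D, np.zeros(len(D), dtype=int)])
        more = permutation_removal(padded, n_perm=3000, seed=4)
        # an occasion detecting nothing new cannot push the median up
        # beyond sampling noise
        assert more.point_estimate <= base.point_estimate * 1.05

    def test_all_degenerate_is_explicit_failure(self):
        # disjoint detections: every ordering yields one new detection per
        # occasion, a flat depletion line, hence no finite x-intercept
        D = np.array([[1, 0], [0, 1]])
        est = permutation_removal(D, n_perm=50, seed=0)
        assert est.failed and est.n_degenerate == 50

    def test_below_mln_flagging(self):
        D = np.ones((10, 3), dtype=int)
        est = permutation_removal(D, n_perm=100, seed=0)
        assert est.below_mln is False
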