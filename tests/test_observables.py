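"""Size, gyration-tensor shape and velocity observables."""

import numpy as np
import pytest

from chainexpand.observables import (EnsembleCurves, ShapeTrace, SizeCurve,
                                     asphericity, conventional_prolateness,
                                     ensemble_mean_size, estimate_R0,
                                     estimate_RF, expansion_velocity,
                                     gyration_tensor, prolateness,
                                     radius_of_gyration, shape_eigenvalues)
from chainexpand.theory import StageTwoParams, stage2_size, stage2_velocity


class TestRadiusOfGyration:
    def test_two_beads(self):
        assert radius_of_gyration([[0, 0, 0], [1, 0, 0]]) == pytest.approx(0.5)

    def test_coincident_beads(self):
        assert radius_of_gyration(np.ones((5, 3))) == 0.0

    def test_unit_square(self):
        pos = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]]
        assert radius_of_gyration(pos) == pytest.approx(np.sqrt(0.5))


class TestGyrationTensor:
    def test_collinear_single_axis(self):
        pos = np.array([[x, 0.0, 0.0] for x in range(5)])
        g = gyration_tensor(pos)
        assert g[0, 0] > 0
        assert np.allclose(g.ravel()[1:], 0.0)

    def test_trace_identity(self, rng):
        pos = rng.normal(0, 2, (30, 3))
        g = gyration_tensor(pos)
        assert np.trace(g) == pytest.approx(radius_of_gyration(pos) ** 2,
                                            rel=1e-12)

    def test_against_double_loop_oracle(self, rng):
        pos = rng.normal(0, 1, (10, 3))
        cm = pos.mean(axis=0)
        oracle = np.zeros((3, 3))
        for i in range(10):
            for a in range(3):
                for b in range(3):
                    oracle[a, b] += (pos[i, a] - cm[a]) * (pos[i, b] - cm[b])
        oracle /= 10
        assert np.allclose(gyration_tensor(pos), oracle, atol=1e-12)


class TestShapeEigenvalues:
    @pytest.mark.parametrize("diag, expected", [
        ((3, 1, 2), (3, 2, 1)),
        ((1, 1, 1), (1, 1, 1)),
        ((5, 0, 0), (5, 0, 0)),
    ])
    def test_sorted_descending(self, diag, expected):
        assert np.allclose(shape_eigenvalues(np.diag(diag)), expected)

    def test_asymmetric_rejected(self):
        t = np.diag((1.0, 2.0, 3.0))
        t[0, 1] = 0.5
        with pytest.raises(ValueError):
            shape_eigenvalues(t)


class TestShapeFactors:
    def test_sphere(self):
        assert asphericity(1, 1, 1) == pytest.approx(0.0)
        assert prolateness(1, 1, 1) == pytest.approx(0.0)
        assert conventional_prolateness(1, 1, 1) == pytest.approx(0.0)

    def test_rod(self):
        assert asphericity(1, 0, 0) == pytest.approx(1.0)
        assert prolateness(1, 0, 0) == pytest.approx(1.0)
        assert conventional_prolateness(1, 0, 0) == pytest.approx(2.0)

    def test_disk(self):
        assert prolateness(1, 1, 0) == pytest.approx(-1.0)

    def test_terminal_coil_eigenvalues(self):
        # formula applied to the mean relaxed-coil eigenvalue triple;
        # differs from the ensemble mean of per-snapshot A because the
        # formula does not commute with averaging
        assert asphericity(332.9, 68.6, 22.8) == pytest.approx(0.4669,
                                                               abs=2e-4)

    def test_bounds_on_random_psd(self, rng):
        for _ in range(200):
            ev = np.sort(rng.uniform(0, 5, 3))[::-1]
            a = asphericity(*ev)
            p = prolateness(*ev)
            pc = conventional_prolateness(*ev)
            assert -1e-12 <= a <= 1 + 1e-12
            assert -1 - 1e-9 <= p <= 1 + 1e-9
            assert -0.25 - 1e-9 <= pc <= 2 + 1e-9

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            asphericity(0, 0, 0)
        with pytest.raises(ValueError):
            prolateness(0, 0, 0)


class TestEnsembleMean:
    def test_constant_replicas(self):
        t = np.arange(5.0)
        curves = [SizeCurve(t, np.full(5, 9.0))] * 4
        ens = ensemble_mean_size(curves)
        assert np.allclose(ens.R, 3.0)
        assert np.allclose(ens.stderr, 0.0)

    def test_mean_then_root(self):
        t = np.arange(3.0)
        curves = [SizeCurve(t, np.full(3, 1.0)), SizeCurve(t, np.full(3, 3.0))]
        ens = ensemble_mean_size(curves)
        # mean of Rg^2 first (2.0), then sqrt: sqrt(2), not (1+sqrt 3)/2
        assert np.allclose(ens.R, np.sqrt(2.0))

    def test_replica_permutation_invariance(self, rng):
        t = np.arange(10.0)
        curves = [SizeCurve(t, rng.uniform(1, 4, 10)) for _ in range(6)]
        a = ensemble_mean_size(curves)
        b = ensemble_mean_size(curves[::-1])
        assert np.allclose(a.R, b.R, rtol=1e-14)
        assert np.allclose(a.stderr, b.stderr, rtol=1e-12)

    def test_mismatched_grids_rejected(self):
        c1 = SizeCurve(np.arange(3.0), np.ones(3))
        c2 = SizeCurve(np.arange(1.0, 4.0), np.ones(3))
        with pytest.raises(ValueError):
            ensemble_mean_size([c1, c2])


class TestExpansionVelocity:
    def test_exact_on_quadratics(self):
        # the three-point central formula is exact for f = t^2
        t = np.linspace(0, 10, 21)
        vr, vmax = expansion_velocity(t, t ** 2, zero_initial=False)
        assert np.allclose(vr[1:-1], 2 * t[1:-1], atol=1e-10)
        assert vmax == pytest.approx(vr[-1])

    def test_constant_series(self):
        t = np.linspace(0, 5, 11)
        vr, vmax = expansion_velocity(t, np.full(11, 3.0))
        assert np.allclose(vr, 0.0)
        assert vmax == 0.0

    def test_matches_stage2_law(self):
        p = StageTwoParams(RF=16.0, tau_c=1e3)
        t = np.linspace(50.0, 500.0, 200)
        vr, _ = expansion_velocity(t, stage2_size(t, p), zero_initial=False)
        expected = stage2_velocity(t, p)
        assert np.allclose(vr[1:-1], expected[1:-1], rtol=2e-3)

    def test_differentiate_then_average_commutes(self, rng):
        # linearity: for shared grids the two orders agree identically
        t = np.linspace(0, 10, 31)
        runs = rng.uniform(1, 2, (5, 31))
        va, _ = expansion_velocity(t, runs, zero_initial=False)
        vb = np.gradient(runs.mean(axis=0), t)
        assert np.allclose(va, vb, atol=1e-12)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            expansion_velocity(np.array([0.0, 1.0]), np.array([1.0, 2.0]))

    def test_nonuniform_grid_rejected(self):
        t = np.array([0.0, 1.0, 3.0, 7.0])
        with pytest.raises(ValueError):
            expansion_velocity(t, t ** 2)


class TestEndpointSizes:
    def test_R0_is_initial_value(self):
        ens = EnsembleCurves(times=np.arange(4.0), R=np.array([2., 3, 4, 4]),
                             stderr=np.zeros(4), n_replicas=10)
        assert estimate_R0(ens) == 2.0

    def test_R0_requires_t0(self):
        ens = EnsembleCurves(times=np.arange(1.0, 4.0), R=np.ones(3),
                             stderr=np.zeros(3), n_replicas=1)
        with pytest.raises(ValueError):
            estimate_R0(ens)

    def test_RF_from_exact_master_curve(self):
        tau = 1e3
        t = np.concatenate([[0.0], np.geomspace(0.1, 8 * tau, 400)])
        R = stage2_size(t, StageTwoParams(RF=16.0, tau_c=tau))
        ens = EnsembleCurves(times=t, R=R, stderr=np.zeros_like(t),
                             n_replicas=1)
        est = estimate_RF(ens, tau_c=tau)
        assert est.value == pytest.approx(16.0, rel=5e-3)
        assert not est.provisional

    def test_constant_curve(self):
        t = np.arange(10.0)
        ens = EnsembleCurves(times=t, R=np.full(10, 5.0),
                             stderr=np.zeros(10), n_replicas=1)
        assert estimate_R0(ens) == 5.0
        est = estimate_RF(ens)
        assert est.value == 5.0 and not est.provisional

    def test_monotone_curve_flagged_provisional(self):
        t = np.arange(100.0)
        ens = EnsembleCurves(times=t, R=1.0 + 0.1 * t,
                             stderr=np.zeros(100), n_replicas=1)
        assert estimate_RF(ens).provisional


class TestShapeTrace:
    def test_eigenvalue_sum_equals_rg2(self):
        t = np.arange(3.0)
        ev = np.array([[3.0, 2.0, 1.0], [5.0, 1.0, 0.5], [2.0, 2.0, 2.0]])
        trace = ShapeTrace(t, ev)
        assert np.allclose(trace.rg2, ev.sum(axis=1), rtol=1e-12)

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            ShapeTrace(np.arange(1.0), np.array([[1.0, 2.0, 0.5]]))
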