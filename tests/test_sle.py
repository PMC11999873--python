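"""Schramm's formula, the slit map, the zipper, and kappa estimators."""

import cmath

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flowsle import (
    ChordalTrace,
    DrivingFunction,
    compute_driving_function,
    driving_autocorrelation,
    empirical_left_passage,
    estimate_kappa_lpp,
    fit_kappa_driving,
    inverse_slit_map,
    sample_sle_trace,
    schramm_probability,
    slit_map,
)
from flowsle.sle import PassageGrid


def _hyp2f1_oracle(a, b, c, z, tol=1e-14):
    """Gauss series via the Pfaff transformation (independent of scipy).

    For z < 0 the transformed argument z/(z-1) lies in (0, 1) and the series
    converges geometrically.
    """
    w = z / (z - 1.0)
    term = 1.0
    total = 1.0
    n = 0
    while abs(term) > tol and n < 10000:
        term *= (a + n) * (c - b + n) / ((c + n) * (n + 1)) * w
        total += term
        n += 1
    return (1.0 - z) ** (-a) * total


class TestSchrammFormula:
    def test_symmetry_point(self):
        for kappa in (1.0, 3.0, 6.0, 7.5):
            assert schramm_probability(np.pi / 2, kappa) == pytest.approx(0.5, abs=1e-12)

    def test_reflection_identity(self):
        for kappa in (2.0, 6.0):
            for phi in (np.pi / 3, np.pi / 7, 2.9):
                s = schramm_probability(phi, kappa) + schramm_probability(np.pi - phi, kappa)
                assert s == pytest.approx(1.0, abs=1e-12)

    def test_against_series_oracle(self):
        from scipy.special import gamma

        for kappa, phi in [(6.0, np.pi / 4), (2.0, 2.0), (4.0, 0.3)]:
            ct = 1.0 / np.tan(phi)
            c = gamma(4 / kappa) / (np.sqrt(np.pi) * gamma((8 - kappa) / (2 * kappa)))
            expected = 0.5 + c * ct * _hyp2f1_oracle(0.5, 4 / kappa, 1.5, -(ct**2))
            assert schramm_probability(phi, kappa) == pytest.approx(expected, abs=1e-10)

    def test_monotone_decreasing_in_phi(self):
        phi = np.linspace(0.05, np.pi - 0.05, 200)
        for kappa in (1.0, 6.0):
            p = schramm_probability(phi, kappa)
            assert np.all(np.diff(p) < 0)
            assert np.all((p > 0) & (p < 1))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            schramm_probability(0.0, 6.0)
        with pytest.raises(ValueError):
            schramm_probability(np.pi / 2, 8.0)


class TestSlitMap:
    def test_tip_maps_to_base(self):
        delta, Delta = 1.0, 0.25
        tip = delta + 2j * np.sqrt(Delta)
        assert slit_map(tip, delta, Delta) == pytest.approx(delta + 0j, abs=1e-12)

    def test_far_field_expansion(self):
        # g(z) ~ z + 2*Delta/(z - delta) for |z - delta| >> sqrt(Delta)
        delta, Delta = 0.5, 0.04
        for z in (50.0 + 0j, -40.0 + 0j, 30j, 20 + 10j):
            approx = z + 2 * Delta / (z - delta)
            assert slit_map(z, delta, Delta) == pytest.approx(approx, abs=1e-4)

    def test_pure_imaginary_stays_imaginary(self):
        # direct evaluation: sqrt((3i)^2 + 4) = sqrt(-5) = i*sqrt(5)
        out = slit_map(3j, 0.0, 1.0)
        assert out == pytest.approx(cmath.sqrt((3j) ** 2 + 4.0), abs=1e-12)
        assert out.real == pytest.approx(0.0, abs=1e-12)
        assert out.imag == pytest.approx(np.sqrt(5.0), abs=1e-12)

    def test_inside_slit_rejected(self):
        with pytest.raises(ValueError):
            slit_map(0.5j, 0.0, 1.0)

    @given(st.floats(-3, 3), st.floats(0.01, 2.0),
           st.floats(-5, 5), st.floats(0.0, 5.0))
    @settings(max_examples=100, deadline=None)
    def test_upper_half_plane_preserved(self, delta, Delta, x, y):
        z = complex(x, y)
        if abs(z.real - delta) < 1e-6 and z.imag < 2 * np.sqrt(Delta):
            return
        out = slit_map(z, delta, Delta)
        assert out.imag >= -1e-12

    def test_inverse_roundtrip(self):
        rng = np.random.default_rng(3)
        z = rng.uniform(-3, 3, 50) + 1j * rng.uniform(0.5, 3, 50)
        delta, Delta = 0.7, 0.3
        back = inverse_slit_map(slit_map(z, delta, Delta), delta, Delta)
        np.testing.assert_allclose(back, z, atol=1e-10)


class TestZipper:
    def test_vertical_segment_zero_driving(self):
        z = 1j * np.linspace(0, 1, 60)
        df = compute_driving_function(ChordalTrace(points=z))
        np.testing.assert_allclose(df.values, 0.0, atol=1e-12)
        assert np.all(np.diff(df.times) > 0)
        assert df.capacity == pytest.approx(0.25, rel=1e-6)  # gamma(t)=2i sqrt(t)

    def test_forward_inverse_roundtrip(self):
        rng = np.random.default_rng(11)
        n, dt = 500, 1e-3
        tr = sample_sle_trace(4.0, n, dt, rng=rng)
        df = compute_driving_function(tr, max_points=None)
        dU = np.sqrt(4.0 * dt) * np.random.default_rng(11).standard_normal(n)
        delta = np.concatenate([[0.0], np.cumsum(dU)[:-1]])
        assert len(df.values) == n + 1
        np.testing.assert_allclose(df.values[1:], delta, atol=1e-9)

    def test_roundtrip_converges_with_resolution(self):
        # refine a fixed Brownian driving; the recovered driving must match
        # at increasing resolution (here the discrete round trip is exact,
        # so the error stays at numerical noise for every resolution)
        errs = []
        for n in (200, 400, 800):
            rng = np.random.default_rng(5)
            dW = rng.standard_normal(800)[:n]
            dt = 0.8 / n
            dU = np.sqrt(6.0 * dt) * dW
            delta = np.concatenate([[0.0], np.cumsum(dU)[:-1]])
            from flowsle.sle import _sqrt_upper

            w = delta.astype(complex)
            for j in range(n - 1, -1, -1):
                v = w[j:] - delta[j]
                w[j:] = _sqrt_upper(v * v - 4.0 * dt, v.real) + delta[j]
            trace = ChordalTrace(points=np.concatenate([[0], w]))
            df = compute_driving_function(trace, max_points=None)
            errs.append(np.max(np.abs(df.values[1:] - delta)))
        assert max(errs) < 1e-8

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        tr = sample_sle_trace(6.0, 300, 1e-3, rng=rng)
        df1 = compute_driving_function(tr, max_points=None)
        s = 2.5
        df2 = compute_driving_function(ChordalTrace(points=s * tr.points), max_points=None)
        np.testing.assert_allclose(df2.times, s**2 * df1.times, rtol=1e-9)
        np.testing.assert_allclose(df2.values, s * df1.values, atol=1e-9)

    def test_rejects_bad_traces(self):
        with pytest.raises(ValueError):
            compute_driving_function(np.array([0, 1j]))  # too short
        with pytest.raises(ValueError):
            compute_driving_function(np.concatenate([[0.5 + 1j], 1j * np.arange(1, 20)]))
        with pytest.raises(ValueError):
            ChordalTrace(points=np.array([0, 1j, 1 - 1j]))  # below the axis


class TestLeftPassage:
    def test_vertical_line_indicators(self):
        z = 1j * np.arange(200.0)
        grid = empirical_left_passage([z], points=np.array([10 * np.exp(1j * np.pi / 4),
                                                            10 * np.exp(3j * np.pi / 4)]))
        # point at phi=pi/4 lies right of the upward line: passed on the left
        assert grid.counts_left[0] == 1
        assert grid.counts_left[1] == 0

    @pytest.mark.parametrize("kappa", [3.0, 6.0])
    def test_self_consistency_exact_probabilities(self, kappa):
        phi = np.linspace(np.pi / 10, 9 * np.pi / 10, 9)
        pts = np.concatenate([r * np.exp(1j * phi) for r in (1.0, 2.0)])
        n = 200000
        P = schramm_probability(np.angle(pts), kappa)
        grid = PassageGrid(points=pts, counts_left=np.round(P * n),
                           n_samples=np.full(pts.size, float(n)))
        est = estimate_kappa_lpp(grid)
        assert est.kappa == pytest.approx(kappa, abs=0.01)
        assert est.method == "left_passage"

    def test_degenerate_grid_rejected(self):
        pts = np.array([1j, 2j, 1 + 1j])
        grid = PassageGrid(points=pts, counts_left=np.zeros(3), n_samples=np.full(3, 10.0))
        with pytest.raises(ValueError):
            estimate_kappa_lpp(grid)


class TestDrivingStatistics:
    @staticmethod
    def _brownian_dfs(kappa, n_paths=400, n_steps=200, T=1.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, T, n_steps + 1)
        out = []
        for _ in range(n_paths):
            dU = np.sqrt(kappa * T / n_steps) * rng.standard_normal(n_steps)
            out.append(DrivingFunction(times=t, values=np.concatenate([[0], np.cumsum(dU)])))
        return out

    @pytest.mark.parametrize("kappa", [2.0, 6.0])
    def test_brownian_slope_recovered(self, kappa):
        est = fit_kappa_driving(self._brownian_dfs(kappa, 500))
        assert est.kappa == pytest.approx(kappa, abs=3.5 * est.stderr)
        assert abs(est.kappa - kappa) < 0.12 * kappa

    def test_collapse_is_standard_normal(self):
        est = fit_kappa_driving(self._brownian_dfs(6.0, 600, seed=2))
        for frac, diag in est.diagnostics["collapse"].items():
            assert diag["n"] >= 500
            assert diag["ks"] < 0.06

    def test_independent_increments_uncorrelated(self):
        dfs = self._brownian_dfs(6.0, 500, seed=3)
        taus, C = driving_autocorrelation(dfs)
        assert C[0] == pytest.approx(1.0, abs=1e-9)
        assert np.nanmax(np.abs(C[1:])) < 0.05

    def test_duplicated_increments_correlate(self):
        rng = np.random.default_rng(4)
        t = np.linspace(0, 1, 65)
        dfs = []
        for _ in range(200):
            base = rng.standard_normal(32)
            dU = np.repeat(base, 2)  # each increment duplicated at lag 1
            dfs.append(DrivingFunction(times=t, values=np.concatenate([[0], np.cumsum(dU)])))
        taus, C = driving_autocorrelation(dfs, n_grid=64)
        assert C[1] > 0.45  # half the lag-1 pairs share an increment

    def test_ar1_increments(self):
        rng = np.random.default_rng(5)
        t = np.linspace(0, 1, 129)
        rho = 0.5
        dfs = []
        for _ in range(400):
            eps = rng.standard_normal(128)
            dU = np.empty(128)
            dU[0] = eps[0]
            for i in range(1, 128):
                dU[i] = rho * dU[i - 1] + np.sqrt(1 - rho**2) * eps[i]
            dfs.append(DrivingFunction(times=t, values=np.concatenate([[0], np.cumsum(dU)])))
        taus, C = driving_autocorrelation(dfs, n_grid=128)
        assert C[1] == pytest.approx(rho, abs=0.05)
        assert C[2] == pytest.approx(rho**2, abs=0.06)
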