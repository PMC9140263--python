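import datetime as dt

import numpy as np
import pytest

from cetamove.geodesy import AzimuthalEquidistant
from cetamove.ssm import (CrwModel, ellipse_to_covariance,
                          observation_covariances, simulate_ctcrw)
from tests.conftest import UTC, make_obs

CENTER = (-20.0, 45.0)


def obs_from_xy(times_s, xy, t0=None, qc="1", smaj=900.0, smin=600.0, orient=30.0):
    t0 = t0 or dt.datetime(2019, 1, 8, tzinfo=UTC)
    proj = AzimuthalEquidistant(*CENTER)
    out = []
    for t, (x, y) in zip(times_s, xy):
        lon, lat = proj.inverse(x, y)
        out.append(make_obs(t0 + dt.timedelta(seconds=float(t)), lon, lat, qc,
                            smaj=smaj, smin=smin, orient=orient))
    return out


class TestEllipseCovariance:
    def test_north_aligned_major_axis(self):
        C = ellipse_to_covariance(1000.0, 500.0, 0.0)
        assert C[1, 1] == pytest.approx(1000.0**2)   # north gets major variance
        assert C[0, 0] == pytest.approx(500.0**2)
        assert C[0, 1] == pytest.approx(0.0, abs=1e-6)

    def test_east_aligned_after_90_degrees(self):
        C = ellipse_to_covariance(1000.0, 500.0, 90.0)
        assert C[0, 0] == pytest.approx(1000.0**2)
        assert C[1, 1] == pytest.approx(500.0**2)

    def test_rotation_preserves_eigenvalues(self):
        C = ellipse_to_covariance(1234.0, 321.0, 37.0)
        ev = np.sort(np.linalg.eigvalsh(C))
        assert ev[1] == pytest.approx(1234.0**2)
        assert ev[0] == pytest.approx(321.0**2)

    def test_class_fallback_when_no_ellipse(self, t0):
        obs = [make_obs(t0, -20.0, 45.0, "B")]
        R = observation_covariances(obs)
        np.testing.assert_allclose(R[0], np.eye(2) * 10000.0**2)


def brute_force_smoother(times_s, y, R, beta, tau, p0_var):
    """Joint-Gaussian conditioning oracle for the CTCRW smoother.

    Builds the full joint covariance of states by forward accumulation and
    conditions on all observations at once; independent of the Kalman code.
    """
    from cetamove.ssm import _ctcrw_tq

    n = len(times_s)
    dim = 4 * n
    # prior mean zero-velocity at first obs position; propagate linearly
    T_full = np.eye(dim)
    Ts = []
    Qs = []
    for i in range(1, n):
        dtv = times_s[i] - times_s[i - 1]
        phi, t01, qxx, qxv, qvv = _ctcrw_tq(beta, tau, dtv)
        T = np.array([[1, t01, 0, 0], [0, phi, 0, 0],
                      [0, 0, 1, t01], [0, 0, 0, phi]])
        Q = np.array([[qxx, qxv, 0, 0], [qxv, qvv, 0, 0],
                      [0, 0, qxx, qxv], [0, 0, qxv, qvv]])
        Ts.append(T)
        Qs.append(Q)
    m0 = np.zeros(4)
    m0[0], m0[2] = y[0]
    P0 = np.diag([p0_var, tau**2, p0_var, tau**2])
    means = [m0]
    for T in Ts:
        means.append(T @ means[-1])
    mean = np.concatenate(means)
    # joint covariance via state-space recursion
    cov = np.zeros((dim, dim))
    cov[:4, :4] = P0
    for i in range(1, n):
        T = Ts[i - 1]
        for j in range(i):
            blk = cov[4 * (i - 1):4 * i, 4 * j:4 * (j + 1)]
            cov[4 * i:4 * (i + 1), 4 * j:4 * (j + 1)] = T @ blk
            cov[4 * j:4 * (j + 1), 4 * i:4 * (i + 1)] = (T @ blk).T
        Pii = T @ cov[4 * (i - 1):4 * i, 4 * (i - 1):4 * i] @ T.T + Qs[i - 1]
        cov[4 * i:4 * (i + 1), 4 * i:4 * (i + 1)] = Pii
    H = np.zeros((2 * n, dim))
    Rbig = np.zeros((2 * n, 2 * n))
    for i in range(n):
        H[2 * i, 4 * i] = 1.0
        H[2 * i + 1, 4 * i + 2] = 1.0
        Rbig[2 * i:2 * i + 2, 2 * i:2 * i + 2] = R[i]
    S = H @ cov @ H.T + Rbig
    K = cov @ H.T @ np.linalg.inv(S)
    post = mean + K @ (y.reshape(-1) - H @ mean)
    return post.reshape(n, 4)


class TestCrwModel:
    def test_noiseless_constant_velocity_recovered_on_line(self):
        times = np.arange(60) * 3600.0
        xy = np.column_stack([times * 1.0, times * 0.5])  # 1.0 / 0.5 m/s
        obs = obs_from_xy(times, xy, smaj=1.0, smin=1.0, orient=0.0)
        model = CrwModel(obs, center=CENTER)
        res = model.fit()
        track = res.predict(interval_hours=6.0)
        # predicted positions sit on the straight line (residual ~ metres)
        expected_x = np.arange(len(track)) * 6 * 3600.0
        np.testing.assert_allclose(track["x"], expected_x, atol=50.0)
        np.testing.assert_allclose(track["y"], expected_x * 0.5, atol=50.0)

    def test_smoother_matches_joint_gaussian_oracle(self):
        rng = np.random.default_rng(42)
        beta, tau = 1.0 / (6 * 3600), 0.8
        times = np.array([0.0, 3600, 9000, 14400, 25000, 36000])
        z = simulate_ctcrw(beta, tau, times, rng=rng)
        y = z[:, [0, 2]] + rng.normal(0, 500, (6, 2))
        obs = obs_from_xy(times, y, smaj=500.0, smin=500.0, orient=0.0)
        model = CrwModel(obs, center=CENTER)
        _, ms, _ = model._smooth(beta, tau)
        expected = brute_force_smoother(times, model.y, model.R, beta, tau,
                                        p0_var=float(model.R[0].trace()))
        np.testing.assert_allclose(ms, expected, atol=1e-6)

    def test_parameter_recovery_within_ci(self):
        rng = np.random.default_rng(1)
        beta, tau = 1.0 / (6 * 3600), 1.0
        times = np.cumsum(rng.exponential(3600.0, 400))
        z = simulate_ctcrw(beta, tau, times, rng=rng)
        y = z[:, [0, 2]] + rng.normal(0, 600, (len(times), 2))
        obs = obs_from_xy(times, y, smaj=600.0, smin=600.0, orient=0.0)
        res = CrwModel(obs, center=CENTER).fit()
        ci = res.conf_int_log()
        assert ci[0, 0] < np.log(beta) < ci[0, 1]
        assert ci[1, 0] < np.log(tau) < ci[1, 1]

    def test_prediction_count_and_speed(self):
        times = np.arange(0, 10 * 86400 + 1, 4 * 3600, dtype=float)
        xy = np.column_stack([times * 1.5, np.zeros_like(times)])
        obs = obs_from_xy(times, xy, smaj=10.0, smin=10.0, orient=0.0)
        track = CrwModel(obs, center=CENTER).fit().predict(6.0)
        assert len(track) == 4 * 10 + 1
        # 1.5 m/s eastward: 32.4 km per 6-h step
        assert track["speed_over_ground"].iloc[5] == pytest.approx(1.5, abs=0.02)

    def test_observation_error_inflates_uncertainty(self):
        times = np.arange(50) * 6 * 3600.0
        rng = np.random.default_rng(3)
        z = simulate_ctcrw(1 / (6 * 3600), 1.0, times, rng=rng)
        xy = z[:, [0, 2]]
        var_small = CrwModel(obs_from_xy(times, xy, smaj=300.0, smin=300.0),
                             center=CENTER)._smooth(1 / (6 * 3600), 1.0)[2]
        var_big = CrwModel(obs_from_xy(times, xy, smaj=3000.0, smin=3000.0),
                           center=CENTER)._smooth(1 / (6 * 3600), 1.0)[2]
        assert np.all(var_big[:, 0, 0] >= var_small[:, 0, 0] - 1e-9)

    def test_degenerate_time_axis_rejected(self, t0):
        obs = [make_obs(t0, -20.0, 45.0), make_obs(t0, -20.1, 45.1)]
        with pytest.raises(ValueError, match="simultaneous"):
            CrwModel(obs, center=CENTER)

    def test_nonpositive_interval_rejected(self):
        times = np.arange(30) * 6 * 3600.0
        xy = np.column_stack([times, np.zeros_like(times)])
        obs = obs_from_xy(times, xy)
        res = CrwModel(obs, center=CENTER).fit()
        with pytest.raises(ValueError):
            res.predict(0.0)
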