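"""Continuous-time correlated random walk (CTCRW) state-space model.

The track is modelled per planar axis as an integrated Ornstein--Uhlenbeck
velocity process: velocity decays toward zero with rate ``beta`` (autocorrelation
time scale ``1/beta``) and has stationary standard deviation ``tau`` (m/s);
position is the integral of velocity.  Between two fixes ``dt`` seconds apart
the transition is exact (no Euler discretisation), so irregular Argos sampling
is handled without interpolation.  Each Argos fix is observed through an
anisotropic Gaussian error whose 2x2 covariance comes from the CLS error
ellipse (semi-major/semi-minor axes and orientation clockwise from north);
fixes without an ellipse fall back to class-based isotropic standard
deviations.

``CrwModel`` holds the data and projection; ``CrwModel.fit()`` maximises the
exact Kalman-filter likelihood and returns a ``CrwResults`` with parameter
estimates, standard errors (log scale), and ``predict()`` for regular-interval
smoothed states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .geodesy import AzimuthalEquidistant, geodesic_inverse
from .io_formats import ArgosObservation

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap


#: Isotropic observation SDs (m) by Argos class when no error ellipse is given.
CLASS_DEFAULT_SD = {"3": 250.0, "2": 500.0, "1": 1500.0, "0": 4000.0,
                    "A": 6000.0, "B": 10000.0}


class ConvergenceError(RuntimeError):
    pass


def ellipse_to_covariance(semi_major, semi_minor, orientation_deg):
    """2x2 east/north covariance from an Argos error ellipse.

    Variances are the squared semi-axes; the major axis points ``orientation``
    degrees clockwise from north, i.e. along (sin O, cos O) in (east, north).
    """
    th = np.radians(orientation_deg)
    e1 = np.array([np.sin(th), np.cos(th)])   # major axis direction
    e2 = np.array([np.cos(th), -np.sin(th)])  # minor axis direction
    return (semi_major**2) * np.outer(e1, e1) + (semi_minor**2) * np.outer(e2, e2)


def observation_covariances(obs, default_sd=None) -> np.ndarray:
    """Per-fix 2x2 observation covariances (ellipse, else class default)."""
    default_sd = default_sd or CLASS_DEFAULT_SD
    R = np.empty((len(obs), 2, 2))
    for i, o in enumerate(obs):
        if (o.ellipse_semi_major is not None and o.ellipse_semi_minor is not None
                and o.ellipse_orientation is not None and o.ellipse_semi_major > 0):
            R[i] = ellipse_to_covariance(
                o.ellipse_semi_major, o.ellipse_semi_minor, o.ellipse_orientation
            )
        else:
            sd = default_sd[o.quality_class]
            R[i] = np.eye(2) * sd**2
    return R


@njit(cache=False)
def _ctcrw_tq(beta, tau, dt):
    """Exact transition (per-axis 2x2) and process covariance over dt seconds."""
    phi = np.exp(-beta * dt)
    sig2 = 2.0 * beta * tau * tau      # velocity diffusion variance rate
    t01 = (1.0 - phi) / beta
    qxx = sig2 / beta**2 * (dt - 2.0 * (1.0 - phi) / beta + (1.0 - phi * phi) / (2.0 * beta))
    qxv = sig2 / (2.0 * beta**2) * (1.0 - phi) ** 2
    qvv = tau * tau * (1.0 - phi * phi)
    return phi, t01, qxx, qxv, qvv


@njit(cache=False)
def _kalman_core(beta, tau, dts, y, R, obs_mask, p0_var, store):
    """Kalman filter (and storage for smoothing) for the 4D CTCRW state.

    State order: [x, vx, y, vy].  ``dts[i]`` is the gap preceding time i
    (dts[0] unused).  ``obs_mask[i]`` marks times with an observation;
    ``y``/``R`` are indexed by time (rows where obs_mask is False ignored).
    Returns (loglik, n_obs_used, m_pred, P_pred, m_filt, P_filt) where the
    arrays are filled only when ``store`` is True.
    """
    n = dts.shape[0]
    m = np.zeros(4)
    m[0] = y[0, 0]
    m[2] = y[0, 1]
    P = np.zeros((4, 4))
    P[0, 0] = p0_var
    P[2, 2] = p0_var
    P[1, 1] = tau * tau
    P[3, 3] = tau * tau

    m_pred = np.zeros((n, 4))
    P_pred = np.zeros((n, 4, 4))
    m_filt = np.zeros((n, 4))
    P_filt = np.zeros((n, 4, 4))

    ll = 0.0
    nobs = 0
    for i in range(n):
        if i > 0:
            phi, t01, qxx, qxv, qvv = _ctcrw_tq(beta, tau, dts[i])
            # per-axis transition applied to mean
            mx = m[0] + t01 * m[1]
            mvx = phi * m[1]
            my = m[2] + t01 * m[3]
            mvy = phi * m[3]
            m = np.array([mx, mvx, my, mvy])
            # P' = T P T^T + Q with T block diagonal per axis
            T = np.zeros((4, 4))
            T[0, 0] = 1.0
            T[0, 1] = t01
            T[1, 1] = phi
            T[2, 2] = 1.0
            T[2, 3] = t01
            T[3, 3] = phi
            P = T @ P @ T.T
            P[0, 0] += qxx
            P[0, 1] += qxv
            P[1, 0] += qxv
            P[1, 1] += qvv
            P[2, 2] += qxx
            P[2, 3] += qxv
            P[3, 2] += qxv
            P[3, 3] += qvv
        if store:
            m_pred[i] = m
            P_pred[i] = P

        if obs_mask[i]:
            # innovation on (x, y)
            v0 = y[i, 0] - m[0]
            v1 = y[i, 1] - m[2]
            s00 = P[0, 0] + R[i, 0, 0]
            s01 = P[0, 2] + R[i, 0, 1]
            s11 = P[2, 2] + R[i, 1, 1]
            det = s00 * s11 - s01 * s01
            if det <= 0:
                return -np.inf, nobs, m_pred, P_pred, m_filt, P_filt
            i00 = s11 / det
            i01 = -s01 / det
            i11 = s00 / det
            ll += -np.log(2.0 * np.pi) - 0.5 * np.log(det) - 0.5 * (
                v0 * (i00 * v0 + i01 * v1) + v1 * (i01 * v0 + i11 * v1)
            )
            nobs += 1
            # K = P H^T S^-1, H picks rows 0 and 2
            PH = np.empty((4, 2))
            for r in range(4):
                PH[r, 0] = P[r, 0]
                PH[r, 1] = P[r, 2]
            K = np.empty((4, 2))
            for r in range(4):
                K[r, 0] = PH[r, 0] * i00 + PH[r, 1] * i01
                K[r, 1] = PH[r, 0] * i01 + PH[r, 1] * i11
            for r in range(4):
                m[r] = m[r] + K[r, 0] * v0 + K[r, 1] * v1
            P = P - K @ PH.T
            P = 0.5 * (P + P.T)
        if store:
            m_filt[i] = m
            P_filt[i] = P
    return ll, nobs, m_pred, P_pred, m_filt, P_filt


@njit(cache=False)
def _rts_smooth(beta, tau, dts, m_pred, P_pred, m_filt, P_filt):
    """Rauch-Tung-Striebel backward pass; returns smoothed means/covariances."""
    n = dts.shape[0]
    ms = m_filt.copy()
    Ps = P_filt.copy()
    for i in range(n - 2, -1, -1):
        phi, t01, _, _, _ = _ctcrw_tq(beta, tau, dts[i + 1])
        T = np.zeros((4, 4))
        T[0, 0] = 1.0
        T[0, 1] = t01
        T[1, 1] = phi
        T[2, 2] = 1.0
        T[2, 3] = t01
        T[3, 3] = phi
        # J = P_filt T^T P_pred^{-1}
        J = P_filt[i] @ T.T @ np.linalg.inv(P_pred[i + 1])
        ms[i] = m_filt[i] + J @ (ms[i + 1] - m_pred[i + 1])
        Ps[i] = P_filt[i] + J @ (Ps[i + 1] - P_pred[i + 1]) @ J.T
        Ps[i] = 0.5 * (Ps[i] + Ps[i].T)
    return ms, Ps


@dataclass
class CrwResults:
    """Fitted CTCRW parameters plus smoothing/prediction facilities."""

    model: "CrwModel"
    beta: float                 # 1/s, inverse velocity autocorrelation time scale
    tau: float                  # m/s, stationary velocity SD
    error_inflation: float      # multiplier applied to observation covariances
    loglik: float
    converged: bool
    se_log: tuple[float, float] | None = None  # SEs of (log beta, log tau)

    @property
    def timescale_hours(self) -> float:
        return 1.0 / self.beta / 3600.0

    def conf_int_log(self, level=0.95):
        """CIs for (log beta, log tau) from the observed information."""
        from scipy.stats import norm

        if self.se_log is None:
            raise ValueError("standard errors unavailable (Hessian failed)")
        z = norm.ppf(0.5 + level / 2.0)
        est = np.log([self.beta, self.tau])
        se = np.asarray(self.se_log)
        return np.column_stack([est - z * se, est + z * se])

    def summary(self) -> str:
        lines = [
            "Continuous-time correlated random walk fit",
            "=" * 44,
            f"observations:        {len(self.model.obs)}",
            f"log-likelihood:      {self.loglik:.2f}",
            f"converged:           {self.converged}",
            f"beta (1/s):          {self.beta:.3e}  (time scale "
            f"{self.timescale_hours:.2f} h)",
            f"tau (m/s):           {self.tau:.3f}",
            f"error inflation:     {self.error_inflation:.3f}",
        ]
        if self.se_log is not None:
            ci = self.conf_int_log()
            lines.append(
                f"95% CI log beta:     [{ci[0,0]:.3f}, {ci[0,1]:.3f}]"
            )
            lines.append(
                f"95% CI log tau:      [{ci[1,0]:.3f}, {ci[1,1]:.3f}]"
            )
        return "\n".join(lines)

    def plot_track(self, interval_hours: float = 6.0, ax=None):
        """Observed fixes and the smoothed path (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        obs_lon = [o.lon for o in self.model.obs]
        obs_lat = [o.lat for o in self.model.obs]
        ax.plot(obs_lon, obs_lat, ".", ms=2, alpha=0.4, label="Argos fixes")
        tr = self.predict(interval_hours)
        ax.plot(tr["lon"], tr["lat"], "-", lw=1.2, label="smoothed path")
        ax.set_xlabel("longitude")
        ax.set_ylabel("latitude")
        ax.legend()
        return ax

    def smooth(self, extra_times=None):
        """Smoothed states at observation times union ``extra_times``.

        Returns (times, means (n,4), covariances (n,4,4)) with state order
        [x, vx, y, vy] in the working projection.
        """
        return self.model._smooth(self.beta, self.tau, self.error_inflation, extra_times)

    def predict(self, interval_hours: float = 6.0) -> pd.DataFrame:
        """Regular-interval smoothed track.

        Steps run from the first fix time in steps of ``interval_hours``
        through the last fix.  ``speed_over_ground`` is the geodesic
        displacement to the next step divided by the interval (the final step
        repeats the preceding value).
        """
        if interval_hours <= 0:
            raise ValueError("prediction interval must be positive")
        t0 = self.model.times[0]
        t1 = self.model.times[-1]
        step = np.timedelta64(int(interval_hours * 3600), "s")
        grid = np.arange(t0, t1 + step, step)
        grid = grid[grid <= t1]
        times, ms, Ps = self.smooth(extra_times=grid)
        sel = np.isin(times, grid)
        times, ms, Ps = times[sel], ms[sel], Ps[sel]

        lon, lat = self.model.projection.inverse(ms[:, 0], ms[:, 2])
        lon = np.atleast_1d(lon)
        lat = np.atleast_1d(lat)
        n = len(times)
        vg = np.zeros(n)
        dt = interval_hours * 3600.0
        dist = np.zeros(n)
        for i in range(n - 1):
            d, _ = geodesic_inverse(lon[i], lat[i], lon[i + 1], lat[i + 1])
            dist[i] = d
            vg[i] = d / dt
        if n > 1:
            vg[-1] = vg[-2]
            dist[-1] = 0.0
        return pd.DataFrame(
            {
                "timestamp": pd.to_datetime(times, utc=True),
                "lon": lon,
                "lat": lat,
                "x": ms[:, 0],
                "y": ms[:, 2],
                "var_x": Ps[:, 0, 0],
                "var_y": Ps[:, 2, 2],
                "step_distance_m": dist,
                "speed_over_ground": vg,
            }
        )


class CrwModel:
    """CTCRW state-space model of a projected Argos track.

    Parameters
    ----------
    obs : list of ArgosObservation
        Time-sorted, prefiltered fixes (>= 20 spanning >= 2 days for `fit`).
    center : (lon, lat), optional
        Azimuthal-equidistant projection centre; defaults to the track's
        midpoint in longitude/latitude range.
    default_sd : dict, optional
        Class -> isotropic SD (m) fallback for fixes without error ellipses.
    """

    def __init__(self, obs: list[ArgosObservation], center=None, default_sd=None):
        if len(obs) < 2:
            raise ValueError("need at least two observations")
        times = np.array([np.datetime64(o.timestamp.replace(tzinfo=None), "ns")
                          for o in obs])
        if np.any(np.diff(times) < np.timedelta64(0, "ns")):
            raise ValueError("observations must be time-sorted")
        if times[0] == times[-1]:
            raise ValueError("degenerate time axis: all fixes simultaneous")
        self.obs = obs
        self.times = times
        if center is None:
            lons = [o.lon for o in obs]
            lats = [o.lat for o in obs]
            center = ((min(lons) + max(lons)) / 2.0, (min(lats) + max(lats)) / 2.0)
        self.projection = AzimuthalEquidistant(*center)
        xy = np.array([self.projection.forward(o.lon, o.lat) for o in obs])
        self.y = xy
        self.R = observation_covariances(obs, default_sd)
        self._tsec = (times - times[0]) / np.timedelta64(1, "s")
        self._dts = np.concatenate([[0.0], np.diff(self._tsec)])
        # collapse exactly-simultaneous fixes is handled upstream (read_argos)

    # -- likelihood ---------------------------------------------------------
    def loglike(self, beta, tau, error_inflation=1.0) -> float:
        mask = np.ones(len(self.obs), dtype=np.bool_)
        ll, _, *_ = _kalman_core(
            beta, tau, self._dts, self.y, self.R * error_inflation, mask,
            float(self.R[0].trace()), False,
        )
        return float(ll)

    def _negll_logparams(self, theta, inflate):
        beta = np.exp(theta[0])
        tau = np.exp(theta[1])
        psi = np.exp(theta[2]) if inflate else 1.0
        ll = self.loglike(beta, tau, psi)
        return -ll if np.isfinite(ll) else 1e12

    def fit(self, starts=None, inflate_errors=False) -> CrwResults:
        """Maximum-likelihood fit of (beta, tau) [and error inflation].

        Runs a quasi-Newton optimisation from three documented starting
        points (velocity time scales of 1, 6 and 24 hours, empirical speed
        scale); the best likelihood wins.
        """
        if len(self.obs) < 20:
            raise ValueError("need >= 20 observations to fit")
        span_days = (self.times[-1] - self.times[0]) / np.timedelta64(1, "D")
        if span_days < 2:
            raise ValueError("need >= 2 days of data to fit")

        dt = np.diff(self._tsec)
        disp = np.linalg.norm(np.diff(self.y, axis=0), axis=1)
        ok = dt > 0
        v_emp = np.median(disp[ok] / dt[ok]) if ok.any() else 1.0
        v_emp = max(v_emp, 0.05)
        if starts is None:
            starts = [
                (np.log(1.0 / (6 * 3600.0)), np.log(v_emp)),
                (np.log(1.0 / (1 * 3600.0)), np.log(2 * v_emp)),
                (np.log(1.0 / (24 * 3600.0)), np.log(0.5 * v_emp)),
            ]

        best = None
        for s in starts:
            x0 = list(s) + ([0.0] if inflate_errors else [])
            res = minimize(
                self._negll_logparams, x0, args=(inflate_errors,),
                method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise ConvergenceError("CTCRW optimisation failed from all starts")

        theta = best.x
        beta, tau = float(np.exp(theta[0])), float(np.exp(theta[1]))
        psi = float(np.exp(theta[2])) if inflate_errors else 1.0

        se = self._se_logparams(theta, inflate_errors)
        return CrwResults(
            model=self, beta=beta, tau=tau, error_inflation=psi,
            loglik=-float(best.fun), converged=bool(best.success or best.fun < 1e11),
            se_log=se,
        )

    def _se_logparams(self, theta, inflate):
        """Numeric observed-information SEs on the log-parameter scale."""
        k = len(theta)
        h = 1e-3
        H = np.zeros((k, k))
        f0 = self._negll_logparams(theta, inflate)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k)
                ej = np.zeros(k)
                ei[i] = h
                ej[j] = h
                fpp = self._negll_logparams(theta + ei + ej, inflate)
                fpm = self._negll_logparams(theta + ei - ej, inflate)
                fmp = self._negll_logparams(theta - ei + ej, inflate)
                fmm = self._negll_logparams(theta - ei - ej, inflate)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
        try:
            cov = np.linalg.inv(H)
            d = np.diag(cov)
            if np.any(d <= 0):
                return None
            return tuple(np.sqrt(d[:2]))
        except np.linalg.LinAlgError:
            return None

    # -- smoothing ----------------------------------------------------------
    def _smooth(self, beta, tau, psi=1.0, extra_times=None):
        times = self.times
        y = self.y
        R = self.R * psi
        mask = np.ones(len(times), dtype=np.bool_)
        if extra_times is not None and len(extra_times):
            extra = np.asarray(extra_times, dtype="datetime64[ns]")
            extra = extra[~np.isin(extra, times)]
            all_times = np.concatenate([times, extra])
            order = np.argsort(all_times, kind="stable")
            all_times = all_times[order]
            y_all = np.zeros((len(all_times), 2))
            R_all = np.zeros((len(all_times), 2, 2))
            mask_all = np.zeros(len(all_times), dtype=np.bool_)
            src = np.concatenate([np.arange(len(times)), np.full(len(extra), -1)])[order]
            for i, s in enumerate(src):
                if s >= 0:
                    y_all[i] = y[s]
                    R_all[i] = R[s]
                    mask_all[i] = True
            times, y, R, mask = all_times, y_all, R_all, mask_all
            # the filter initialises from the first *observed* position
            first_obs = int(np.argmax(mask))
            if first_obs != 0:
                y[0] = y[first_obs]
        tsec = (times - times[0]) / np.timedelta64(1, "s")
        dts = np.concatenate([[0.0], np.diff(tsec)])
        _, _, m_pred, P_pred, m_filt, P_filt = _kalman_core(
            beta, tau, dts, y, R, mask, float(self.R[0].trace()), True
        )
        ms, Ps = _rts_smooth(beta, tau, dts, m_pred, P_pred, m_filt, P_filt)
        return times, ms, Ps


def simulate_ctcrw(beta, tau, times_s, x0=(0.0, 0.0), v0=None, rng=None):
    """Simulate a CTCRW exactly at the given times (seconds).

    Returns an (n, 4) array of states [x, vx, y, vy].  Initial velocity is
    drawn from the stationary distribution unless given.
    """
    rng = rng or np.random.default_rng()
    times_s = np.asarray(times_s, dtype=float)
    n = len(times_s)
    z = np.zeros((n, 4))
    z[0, 0], z[0, 2] = x0
    if v0 is None:
        z[0, 1], z[0, 3] = rng.normal(0.0, tau, 2)
    else:
        z[0, 1], z[0, 3] = v0
    for i in range(1, n):
        dt = times_s[i] - times_s[i - 1]
        phi, t01, qxx, qxv, qvv = _ctcrw_tq(beta, tau, dt)
        Q = np.array([[qxx, qxv], [qxv, qvv]])
        L = np.linalg.cholesky(Q + 1e-12 * np.eye(2))
        for ax in (0, 2):
            mean = np.array([z[i - 1, ax] + t01 * z[i - 1, ax + 1],
                             phi * z[i - 1, ax + 1]])
            z[i, ax:ax + 2] = mean + L @ rng.standard_normal(2)
    return z
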