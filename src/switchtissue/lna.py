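"""Linear noise approximation (LNA) likelihood for the reporter network.

The reporter network (transcription at piecewise-constant beta(t), linear
degradation and translation) has linear propensities, so its LNA moment
equations are exact for the mean and covariance of the counts:

    d m / dt = A m + (beta, 0)',       A = [[-dm, 0], [alpha, -dp]]
    d V / dt = A V + V A' + Q(m),      Q(m) = diag(beta + dm*m1,
                                                   alpha*m1 + dp*m2)

Observations Y_t = kappa * P_t + eps, eps ~ N(0, sigma2), are assimilated by
a Kalman filter; the marginal likelihood is the product of the one-step
predictive densities.  Between observations the moments are propagated by
closed-form matrix exponentials (A is 2x2 lower triangular), with the
process-noise integral reduced to three precomputed matrices H1, H2, H3 that
multiply (m1, m2, beta) linearly — so the per-step update is a handful of
scalar operations.  Switch times falling between observations are handled by
splitting the step into exact sub-segments.

``dense_kalman_loglik`` provides an independent brute-force reference filter
(Runge-Kutta on the raw moment ODEs at a fine grid) used as a cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import KineticParams, TranscriptionProfile

LOG2PI = math.log(2.0 * math.pi)


@dataclass
class LNAState:
    """Filtered mean/covariance of (mRNA, protein) at one time."""

    mean: np.ndarray          # (2,)
    cov: np.ndarray           # (2, 2) symmetric PSD
    time: float


def stationary_moments(beta: float, kp: KineticParams) -> tuple[float, float, float, float, float]:
    """Stationary (m1, m2, v11, v12, v22) of the network at constant beta."""
    dm, dp, al = kp.delta_m, kp.delta_p, kp.alpha
    m1 = beta / dm
    m2 = al * beta / (dm * dp)
    v11 = m1                      # Poisson birth-death mRNA
    v12 = al * v11 / (dm + dp)
    v22 = (al * v12 + al * beta / dm) / dp
    return m1, m2, v11, v12, v22


class LNAPropagator:
    """Caches closed-form segment propagators for fixed kinetic parameters.

    ``seg(dt)`` returns the scalar tuple
    (e11, e21, e22, r1, r2, h1_11, h1_12, h1_22, h2_22, h3_11, h3_12, h3_22)
    such that over a step of length dt at rate beta:

        m1' = e11 m1 + beta r1
        m2' = e21 m1 + e22 m2 + beta r2
        V'  = E V E' + m1 H1 + m2 H2 + beta H3

    with H2 having only a (2,2) entry.  The H integrals are evaluated by
    Simpson quadrature on closed-form integrands.
    """

    def __init__(self, kp: KineticParams, n_quad: int = 64):
        self.kp = kp
        self.n_quad = n_quad
        self._cache: dict[float, tuple] = {}

    def _e_r(self, s):
        """Vectorised E(s) entries and r(s) = int_0^s E(u) e1 du."""
        dm, dp, al = self.kp.delta_m, self.kp.delta_p, self.kp.alpha
        e11 = np.exp(-dm * s)
        e22 = np.exp(-dp * s)
        if abs(dm - dp) < 1e-9:
            e21 = al * s * e11
            r2 = al * (1.0 - e11 * (1.0 + dm * s)) / dm**2
        else:
            e21 = al * (e22 - e11) / (dm - dp)
            r2 = al * ((1.0 - e22) / dp - (1.0 - e11) / dm) / (dm - dp)
        r1 = (1.0 - e11) / dm
        return e11, e21, e22, r1, r2

    def seg(self, dt: float) -> tuple:
        key = round(dt, 12)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        dm, dp, al = self.kp.delta_m, self.kp.delta_p, self.kp.alpha
        e11, e21, e22, r1, r2 = (float(x) for x in self._e_r(dt))
        # Simpson nodes over s in [0, dt]
        n = self.n_quad
        s = np.linspace(0.0, dt, n + 1)
        wts = np.ones(n + 1)
        wts[1:-1:2] = 4.0
        wts[2:-1:2] = 2.0
        wts *= dt / (3.0 * n)
        E11s, E21s, E22s, R1s, R2s = self._e_r(s)
        B11, B21, B22, _, _ = self._e_r(dt - s)
        # diagonal process-noise coefficients of (m1, m2, beta) at time s
        g1_1 = dm * E11s
        g1_2 = al * E11s + dp * E21s
        g2_2 = dp * E22s
        g3_1 = 1.0 + dm * R1s
        g3_2 = al * R1s + dp * R2s

        def conj(g_1, g_2):
            h11 = float(np.dot(wts, B11**2 * g_1))
            h12 = float(np.dot(wts, B11 * B21 * g_1))
            h22 = float(np.dot(wts, B21**2 * g_1 + B22**2 * g_2))
            return h11, h12, h22

        h1 = conj(g1_1, g1_2)
        h2_22 = float(np.dot(wts, B22**2 * g2_2))
        h3 = conj(g3_1, g3_2)
        out = (e11, e21, e22, r1, r2, *h1, h2_22, *h3)
        self._cache[key] = out
        return out


def _segment_plan(times: np.ndarray, profile: TranscriptionProfile, prop: LNAPropagator):
    """Step rates plus exact sub-segment pieces for steps containing switches.

    Returns ``(betas, special)`` where ``betas[k]`` is the rate over the
    whole step ``times[k] -> times[k+1]`` (valid when no switch falls inside)
    and ``special[k]`` lists (propagator, beta) pieces for split steps.
    """
    sw = profile.switch_times
    rates = profile.rates
    betas = rates[np.searchsorted(sw, times[:-1], side="right")].tolist()
    special: dict[int, list] = {}
    if len(sw):
        steps = np.searchsorted(times, sw, side="left") - 1
        for s_time, k in zip(sw, steps):
            if 0 <= k < len(times) - 1 and times[k] < s_time < times[k + 1]:
                a, b = times[k], times[k + 1]
                inside = sw[(sw > a) & (sw < b)]
                edges = np.concatenate(([a], inside, [b]))
                special[int(k)] = [
                    (
                        prop.seg(float(edges[j + 1] - edges[j])),
                        float(rates[np.searchsorted(sw, edges[j], side="right")]),
                    )
                    for j in range(len(edges) - 1)
                ]
    return betas, special


def lna_loglik(
    times: np.ndarray,
    y: np.ndarray,
    profile: TranscriptionProfile,
    kp: KineticParams,
    init: LNAState | None = None,
    prop: LNAPropagator | None = None,
    return_predictions: bool = False,
):
    """Log marginal likelihood of a fluorescence trace under a profile.

    The initial state defaults to the stationary moments of the first
    segment (tissue is assumed settled before imaging starts).  Returns the
    sum of one-step-ahead predictive log densities, including the first
    observation against the initial predictive.  With
    ``return_predictions=True`` also returns the per-observation predictive
    means and variances of Y (used by recursive residuals).
    """
    times = np.asarray(times, dtype=float)
    y = np.asarray(y, dtype=float)
    kappa, sigma2 = kp.kappa, kp.sigma2
    if prop is None:
        prop = LNAPropagator(kp)
    if init is None:
        m1, m2, v11, v12, v22 = stationary_moments(float(profile.rate_at(times[0])), kp)
    else:
        m1, m2 = float(init.mean[0]), float(init.mean[1])
        v11, v12, v22 = float(init.cov[0, 0]), float(init.cov[0, 1]), float(init.cov[1, 1])
    betas, special = _segment_plan(times, profile, prop)
    n_obs = len(y)
    dt0 = float(times[1] - times[0]) if n_obs > 1 else 0.0
    if n_obs > 1:
        (E11, E21, E22, R1, R2,
         A11, A12, A22, B22, C11, C12, C22) = prop.seg(dt0)
    ll = 0.0
    y_list = y.tolist()
    pred_mean = np.empty(n_obs) if return_predictions else None
    pred_var = np.empty(n_obs) if return_predictions else None
    kap2 = kappa * kappa
    for k in range(n_obs):
        if k > 0:
            pieces = special.get(k - 1)
            if pieces is None:
                beta = betas[k - 1]
                nm1 = E11 * m1 + beta * R1
                nm2 = E21 * m1 + E22 * m2 + beta * R2
                nv11 = E11 * E11 * v11 + m1 * A11 + beta * C11
                nv12 = E11 * (E21 * v11 + E22 * v12) + m1 * A12 + beta * C12
                nv22 = (E21 * E21 * v11 + 2.0 * E21 * E22 * v12 + E22 * E22 * v22
                        + m1 * A22 + m2 * B22 + beta * C22)
                m1, m2, v11, v12, v22 = nm1, nm2, nv11, nv12, nv22
            else:
                for (e11, e21, e22, r1, r2,
                     h1_11, h1_12, h1_22, h2_22,
                     h3_11, h3_12, h3_22), beta in pieces:
                    nm1 = e11 * m1 + beta * r1
                    nm2 = e21 * m1 + e22 * m2 + beta * r2
                    nv11 = e11 * e11 * v11 + m1 * h1_11 + beta * h3_11
                    nv12 = e11 * (e21 * v11 + e22 * v12) + m1 * h1_12 + beta * h3_12
                    nv22 = (e21 * e21 * v11 + 2.0 * e21 * e22 * v12 + e22 * e22 * v22
                            + m1 * h1_22 + m2 * h2_22 + beta * h3_22)
                    m1, m2, v11, v12, v22 = nm1, nm2, nv11, nv12, nv22
        S = kap2 * v22 + sigma2
        if S <= 0.0:
            return (-math.inf, pred_mean, pred_var) if return_predictions else -math.inf
        resid = y_list[k] - kappa * m2
        ll += -0.5 * (LOG2PI + math.log(S) + resid * resid / S)
        if return_predictions:
            pred_mean[k] = kappa * m2
            pred_var[k] = S
        g = kappa / S
        k1g = v12 * g
        k2g = v22 * g
        m1 += k1g * resid
        m2 += k2g * resid
        v11 -= k1g * kappa * v12
        nv12 = v12 - k1g * kappa * v22
        v22 -= k2g * kappa * v22
        v12 = nv12
        if v11 < 0.0 or v22 < 0.0:
            tol = 1e-9 * (abs(v11) + abs(v22) + S)  # relative rounding budget
            if v11 < -tol or v22 < -tol:
                raise FloatingPointError(
                    f"non-PSD filtered covariance at t={times[k]:.4f} h"
                )
            v11 = max(v11, 0.0)
            v22 = max(v22, 0.0)
    if return_predictions:
        return ll, pred_mean, pred_var
    return ll


def dense_kalman_loglik(
    times: np.ndarray,
    y: np.ndarray,
    profile: TranscriptionProfile,
    kp: KineticParams,
    dt: float = 1e-3,
) -> float:
    """Brute-force reference filter: RK4 on the raw moment ODEs.

    Independent of the closed-form path; used only as a numerical oracle.
    """
    times = np.asarray(times, dtype=float)
    y = np.asarray(y, dtype=float)
    dm, dp, al, kappa, sigma2 = kp.delta_m, kp.delta_p, kp.alpha, kp.kappa, kp.sigma2
    A = np.array([[-dm, 0.0], [al, -dp]])

    def deriv(state, beta):
        m = state[:2]
        V = state[2:].reshape(2, 2)
        dmdt = A @ m + np.array([beta, 0.0])
        Q = np.diag([beta + dm * m[0], al * m[0] + dp * m[1]])
        dVdt = A @ V + V @ A.T + Q
        return np.concatenate([dmdt, dVdt.ravel()])

    m1, m2, v11, v12, v22 = stationary_moments(float(profile.rate_at(times[0])), kp)
    state = np.array([m1, m2, v11, v12, v12, v22])
    H = np.array([0.0, kappa])
    ll = 0.0
    for k in range(len(y)):
        if k > 0:
            t = times[k - 1]
            t_end = times[k]
            # integrate piecewise, never stepping across a switch time
            sw = profile.switch_times
            breaks = np.concatenate([sw[(sw > t) & (sw < t_end)], [t_end]])
            for b in breaks:
                while t < b - 1e-12:
                    h = min(dt, b - t)
                    beta = float(profile.rate_at(t))
                    k1 = deriv(state, beta)
                    k2_ = deriv(state + 0.5 * h * k1, beta)
                    k3 = deriv(state + 0.5 * h * k2_, beta)
                    k4 = deriv(state + h * k3, beta)
                    state = state + (h / 6.0) * (k1 + 2 * k2_ + 2 * k3 + k4)
                    t += h
        m = state[:2]
        V = state[2:].reshape(2, 2)
        S = float(H @ V @ H + sigma2)
        if S <= 0:
            return -math.inf
        resid = y[k] - float(H @ m)
        ll += -0.5 * (LOG2PI + math.log(S) + resid * resid / S)
        K = V @ H / S
        m = m + K * resid
        V = V - np.outer(K, H @ V)
        state = np.concatenate([m, V.ravel()])
    return ll
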