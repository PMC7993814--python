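"""Numba-compiled inner loop of the simulated likelihood.

The kernel mirrors :func:`hopitx.likelihood.total_loglik`'s numpy
reference path exactly (same draws, same importance sampler, same
floor); a unit test asserts agreement to near machine precision.  It
exists because maximum-likelihood fitting evaluates the likelihood tens
of thousands of times under numeric differentiation.

If numba is unavailable at import time the pure-python functions are
used as-is (slow but correct).
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


_SQRT2 = math.sqrt(2.0)
_SQRT2PI = math.sqrt(2.0 * math.pi)
_EXP_CLIP = 700.0
_FLOOR = 1e-300  # likelihood floor; log(1e-300) is the floored log-likelihood


@njit(cache=True)
def _phi(x: float) -> float:
    """Standard normal CDF via erfc (accurate in both tails)."""
    return 0.5 * math.erfc(-x / _SQRT2)


@njit(cache=True)
def _cell(lo: float, hi: float) -> float:
    """Phi(hi) - Phi(lo) without cancellation in the upper tail.

    When the interval lies mostly above 0 the difference of CDFs loses
    all precision (both approach 1); the survival-function form keeps
    the small cell masses that deep-tail respondents generate.
    """
    if lo > -hi:
        return _phi(-lo) - _phi(-hi)
    return _phi(hi) - _phi(lo)


@njit(cache=True)
def _ndtri(p: float) -> float:
    """Inverse standard normal CDF.

    Acklam's rational approximation refined by one Halley step; absolute
    error below ~3e-9 before refinement and near machine precision
    after.  Needed inside the jitted kernel, where scipy is not
    callable; validated against ``scipy.special.ndtri`` in the tests.
    """
    if p <= 0.0:
        return -np.inf
    if p >= 1.0:
        return np.inf
    a0, a1, a2 = -3.969683028665376e01, 2.209460984245205e02, -2.759285104469687e02
    a3, a4, a5 = 1.383577518672690e02, -3.066479806614716e01, 2.506628277459239e00
    b0, b1, b2 = -5.447609879822406e01, 1.615858368580409e02, -1.556989798598866e02
    b3, b4 = 6.680131188771972e01, -1.328068155288572e01
    c0, c1, c2 = -7.784894002430293e-03, -3.223964580411365e-01, -2.400758277161838e00
    c3, c4, c5 = -2.549732539343734e00, 4.374664141464968e00, 2.938163982698783e00
    d0, d1, d2, d3 = (
        7.784695709041462e-03,
        3.224671290700398e-01,
        2.445134137142996e00,
        3.754408661907416e00,
    )
    plow = 0.02425
    if p < plow:
        q = math.sqrt(-2.0 * math.log(p))
        x = (((((c0 * q + c1) * q + c2) * q + c3) * q + c4) * q + c5) / (
            (((d0 * q + d1) * q + d2) * q + d3) * q + 1.0
        )
    elif p <= 1.0 - plow:
        q = p - 0.5
        r = q * q
        x = (((((a0 * r + a1) * r + a2) * r + a3) * r + a4) * r + a5) * q / (
            ((((b0 * r + b1) * r + b2) * r + b3) * r + b4) * r + 1.0
        )
    else:
        q = math.sqrt(-2.0 * math.log(1.0 - p))
        x = -(((((c0 * q + c1) * q + c2) * q + c3) * q + c4) * q + c5) / (
            (((d0 * q + d1) * q + d2) * q + d3) * q + 1.0
        )
    e = _phi(x) - p
    un = e * _SQRT2PI * math.exp(0.5 * x * x)
    return x - un / (1.0 + 0.5 * x * un)


@njit(cache=True)
def loglik_kernel(
    y: np.ndarray,  # (N,) int64, 1..K
    V: np.ndarray,  # (N, J) int64, 1..K
    xb: np.ndarray,  # (N,) beta'x_i
    tau_lin: np.ndarray,  # (N, K-1): gamma_k'z_i per threshold
    theta: np.ndarray,  # (J,)
    sigma_u: float,
    sigma_v: float,
    alpha: float,
    u_draws: np.ndarray,  # (R,) standard-normal QMC points for u
    q_draws: np.ndarray,  # (R,) uniform QMC points for the eps sampler
    out: np.ndarray,  # (N,) per-respondent log-likelihood (output)
) -> None:
    """Per-respondent simulated log-likelihood.

    For each quasi-random draw r the cut-point shift is
    ``u_r = u_draws[r]``; the outcome disturbance eps is importance
    sampled from the truncated normal on the interval where the
    self-report indicator is 1 (inverse-CDF of ``q_draws[r]``) and the
    interval's normal mass enters as the weight.  The vignette factors
    use the heteroskedastic scale evaluated at the sampled eps.
    """
    N = y.shape[0]
    R = u_draws.shape[0]
    J = V.shape[1]
    Km1 = tau_lin.shape[1]
    tau = np.empty(Km1)
    for i in range(N):
        acc = 0.0
        for r in range(R):
            tau[0] = tau_lin[i, 0] + sigma_u * u_draws[r]
            for k in range(1, Km1):
                inc = tau_lin[i, k]
                if inc > _EXP_CLIP:
                    inc = _EXP_CLIP
                tau[k] = tau[k - 1] + math.exp(inc)
            yi = y[i]
            # Normal mass of eps on [tau^{y-1} - xb, tau^y - xb): the
            # importance weight.  Work in the shorter tail for accuracy.
            if yi == 1:
                fa = 0.0
                w = _phi(tau[0] - xb[i])
            elif yi == Km1 + 1:
                fa = _phi(tau[Km1 - 1] - xb[i])
                w = _phi(-(tau[Km1 - 1] - xb[i]))
            else:
                fa = _phi(tau[yi - 2] - xb[i])
                w = _cell(tau[yi - 2] - xb[i], tau[yi - 1] - xb[i])
            if w <= 0.0:
                continue
            pp = fa + q_draws[r] * w
            if pp <= 0.0:
                pp = _FLOOR
            elif pp >= 1.0:
                pp = 1.0 - 1e-16
            eps = _ndtri(pp)
            ystar = xb[i] + eps
            term = w
            for j in range(J):
                d = ystar - theta[j]
                ex = alpha * d * d
                if ex > _EXP_CLIP:
                    ex = _EXP_CLIP
                elif ex < -_EXP_CLIP:
                    ex = -_EXP_CLIP
                inv_s = math.exp(-ex) / sigma_v
                kj = V[i, j]
                if kj == 1:
                    pj = _phi((tau[0] - theta[j]) * inv_s)
                elif kj == Km1 + 1:
                    pj = _phi(-(tau[Km1 - 1] - theta[j]) * inv_s)
                else:
                    pj = _cell(
                        (tau[kj - 2] - theta[j]) * inv_s,
                        (tau[kj - 1] - theta[j]) * inv_s,
                    )
                term *= pj
            acc += term
        li = acc / R
        if li < _FLOOR:
            li = _FLOOR
        out[i] = math.log(li)
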