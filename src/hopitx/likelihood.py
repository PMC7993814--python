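"""Simulated log-likelihood of the (extended) HOPIT model.

The individual likelihood is a double integral over the outcome
disturbance eps and the cut-point shift u:

    l_i = E_{eps,u}[ 1{tau_i^{y-1} <= beta'x_i + eps < tau_i^y}
                     * prod_j Pr(V_ij | tau_i(u), theta_j, s_ij(eps)) ]

It is evaluated by quasi-Monte Carlo over a 2-D Halton sequence
(initial points omitted, then thinned by a leap coprime with the Halton
bases; defaults skip=1000, leap=101) with importance
sampling on eps: given u, eps is drawn by inverse-CDF from the
truncated normal on the interval where the self-report indicator is 1,
and the interval's normal mass enters as the weight.  This leaves a
smooth integrand and is unbiased for the inner integral.

Two equivalent implementations exist: a vectorised numpy reference
(this module) and a numba kernel (:mod:`hopitx._kernel`) used during
fitting; they agree to near machine precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import qmc

from ._kernel import loglik_kernel
from .data import HopitParams, SurveyDataset
from .model_core import EXP_CLIP

logger = logging.getLogger(__name__)

#: Log-likelihood floor per respondent: prevents -inf during optimizer
#: excursions into parameter regions inconsistent with an observation.
LOG_FLOOR = np.log(1e-300)


@dataclass(frozen=True)
class QmcDraws:
    """Fixed 2-D Halton-based integration points, shared across evaluations.

    Dimension 1 drives the cut-point shift u (mapped through the inverse
    normal CDF); dimension 2 drives the importance sampler for eps.
    Deterministic given ``(R, skip, leap)``.
    """

    R: int
    uniforms: np.ndarray  # (R, 2), strictly inside (0, 1)
    skip: int = 1000
    leap: int = 101

    @property
    def u_normal(self) -> np.ndarray:
        return ndtri(self.uniforms[:, 0])

    @property
    def q_uniform(self) -> np.ndarray:
        return self.uniforms[:, 1]

    def spec(self) -> tuple[int, int, int]:
        return (self.R, self.skip, self.leap)


def halton_points(R: int, skip: int = 1000, leap: int = 101) -> QmcDraws:
    """2-D Halton sequence omitting ``skip`` initial points, keeping every ``leap``-th.

    The same ``(R, skip, leap)`` always yields bitwise-identical draws,
    so likelihoods (and likelihood-ratio statistics computed from two
    fits sharing one ``QmcDraws``) are deterministic.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    engine = qmc.Halton(d=2, scramble=False)
    engine.fast_forward(skip)
    pts = engine.random(R * leap)[leap - 1 :: leap][:R]
    pts = np.clip(pts, 1e-12, 1 - 1e-12)
    return QmcDraws(R=R, uniforms=np.ascontiguousarray(pts), skip=skip, leap=leap)


@dataclass
class LoglikResult:
    total: float
    per_respondent: np.ndarray
    n_draws: int
    n_floored: int = 0


def _prepare(params: HopitParams, data: SurveyDataset):
    if len(params.beta) != data.p:
        raise ValueError("beta length does not match X columns")
    if params.gamma.shape != (data.K - 1, data.q):
        raise ValueError(
            f"gamma must be (K-1, q) = {(data.K - 1, data.q)}, got {params.gamma.shape}"
        )
    if params.J != data.J:
        raise ValueError("theta length does not match number of vignettes")
    xb = data.X @ params.beta
    tau_lin = data.Z @ params.gamma.T  # (N, K-1): level eq then log-increments
    return xb, tau_lin


def total_loglik(
    params: HopitParams,
    data: SurveyDataset,
    draws: QmcDraws,
    use_kernel: bool = True,
) -> LoglikResult:
    """Simulated log-likelihood ``L = sum_i log l_i`` over the dataset.

    Deterministic given ``draws``; invariant to respondent ordering.
    With ``alpha = 0`` the heteroskedastic factor collapses and the same
    code path evaluates the standard HOPIT likelihood.
    """
    xb, tau_lin = _prepare(params, data)
    out = np.empty(data.n)
    if use_kernel:
        loglik_kernel(
            data.y,
            np.ascontiguousarray(data.V),
            xb,
            np.ascontiguousarray(tau_lin),
            params.theta,
            params.sigma_u,
            params.sigma_v,
            params.alpha,
            draws.u_normal,
            draws.q_uniform,
            out,
        )
    else:
        _reference_loglik(params, data, draws, xb, tau_lin, out)
    n_floored = int(np.sum(out <= LOG_FLOOR + 1e-9))
    if n_floored:
        # expected during optimizer excursions; callers surface it once
        logger.debug(
            "%d respondent(s) hit the likelihood floor (parameters far from data)",
            n_floored,
        )
    return LoglikResult(
        total=float(out.sum()), per_respondent=out, n_draws=draws.R,
        n_floored=n_floored,
    )


def individual_loglik(
    params: HopitParams,
    data: SurveyDataset,
    i: int,
    draws: QmcDraws,
) -> float:
    """Simulated ``log l_i`` for respondent ``i`` (see module docstring)."""
    sub = SurveyDataset(
        y=data.y[i : i + 1],
        V=data.V[i : i + 1],
        X=data.X[i : i + 1],
        Z=data.Z[i : i + 1],
        K=data.K,
    )
    return total_loglik(params, sub, draws).total


def _reference_loglik(params, data, draws, xb, tau_lin, out) -> None:
    """Vectorised numpy path; the readable specification of the estimator."""
    N, J, Km1 = data.n, data.J, data.K - 1
    u = draws.u_normal  # (R,)
    q = draws.q_uniform  # (R,)
    tau = np.empty((N, draws.R, Km1))
    tau[:, :, 0] = tau_lin[:, 0][:, None] + params.sigma_u * u[None, :]
    for k in range(1, Km1):
        tau[:, :, k] = tau[:, :, k - 1] + np.exp(
            np.clip(tau_lin[:, k], -EXP_CLIP, EXP_CLIP)
        )[:, None]
    aug = np.concatenate(
        [
            np.full((N, draws.R, 1), -np.inf),
            tau,
            np.full((N, draws.R, 1), np.inf),
        ],
        axis=2,
    )
    rows = np.arange(N)

    def cell(lo, hi):
        # Phi(hi) - Phi(lo), switching to the survival-function form when
        # the interval sits in the upper tail (mirrors the jitted kernel)
        cdf_form = np.where(
            np.isposinf(hi), 1.0, ndtr(np.where(np.isposinf(hi), 0.0, hi))
        ) - np.where(np.isneginf(lo), 0.0, ndtr(np.where(np.isneginf(lo), 0.0, lo)))
        sf_form = np.where(
            np.isneginf(lo), 1.0, ndtr(np.where(np.isneginf(lo), 0.0, -lo))
        ) - np.where(np.isposinf(hi), 0.0, ndtr(np.where(np.isposinf(hi), 0.0, -hi)))
        with np.errstate(invalid="ignore"):
            use_sf = lo > -hi  # False wherever lo = -inf
        return np.where(use_sf, sf_form, cdf_form)

    lo = aug[rows, :, data.y - 1] - xb[:, None]
    hi = aug[rows, :, data.y] - xb[:, None]
    Fa = np.where(np.isneginf(lo), 0.0, ndtr(np.where(np.isneginf(lo), 0.0, lo)))
    w = cell(lo, hi)  # (N, R) importance weight
    pp = np.clip(Fa + q[None, :] * w, 1e-300, 1 - 1e-16)
    eps = ndtri(pp)
    ystar = xb[:, None] + eps
    lik = np.where(w > 0, w, 0.0)
    for j in range(J):
        d2 = (ystar - params.theta[j]) ** 2
        inv_s = np.exp(-np.clip(params.alpha * d2, -EXP_CLIP, EXP_CLIP)) / params.sigma_v
        hi_j = (aug[rows, :, data.V[:, j]] - params.theta[j]) * inv_s
        lo_j = (aug[rows, :, data.V[:, j] - 1] - params.theta[j]) * inv_s
        lik *= cell(lo_j, hi_j)
    li = lik.mean(axis=1)
    np.log(np.maximum(li, 1e-300), out=out)
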