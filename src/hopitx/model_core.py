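"""Pure model formulas of the (extended) hierarchical ordered probit.

All functions are vectorised and side-effect free; the likelihood,
simulation and evaluation layers are built on top of them.

Model summary
-------------
Latent outcome           ``y*_i = beta'x_i + eps_i``, ``eps_i ~ N(0,1)``.
Observation rule         ``y_i = k  <=>  tau_i^{k-1} <= y*_i < tau_i^k``.
Cut-points               ``tau_i^1 = gamma_1'z_i + sigma_u u_i`` and
                         ``tau_i^k = tau_i^{k-1} + exp(gamma_k'z_i)``.
Vignette perception      ``V*_ij = theta_j + s_ij v_ij``, ``v_ij ~ N(0,1)``,
                         with ``s_ij = sigma_v exp(alpha (y*_i - theta_j)^2)``.
``alpha = 0`` gives the homoskedastic (standard HOPIT) perception model.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr

# Exponent clip before exponentiation; preserves ordering and never binds
# near the optimum for the alpha range of interest (<= 0.05).
EXP_CLIP = 700.0


def latent_index(beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Mean of the latent outcome, ``beta'x_i`` per respondent.

    The full latent value is ``beta'x_i + eps_i`` with the disturbance
    sd fixed at 1 for identification.
    """
    beta = np.asarray(beta, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != beta.shape[0]:
        raise ValueError(
            f"beta length {beta.shape[0]} does not match X columns {X.shape[-1]}"
        )
    return X @ beta


def compute_cutoffs(
    gamma: np.ndarray,
    Z: np.ndarray,
    sigma_u: float,
    u: np.ndarray,
) -> np.ndarray:
    """Finite respondent-specific cut-points, an ``(N, K-1)`` matrix.

    Row ``i`` is ``tau_i^1 < ... < tau_i^{K-1}`` with
    ``tau_i^1 = gamma_1'z_i + sigma_u u_i`` and increments
    ``exp(gamma_k'z_i)`` for ``k >= 2``; the ``+/-inf`` boundary
    conventions (``tau^0``, ``tau^K``) are applied by consumers.
    Strict monotonicity is automatic because the increments are
    exponentials.
    """
    gamma = np.atleast_2d(np.asarray(gamma, dtype=float))
    Z = np.asarray(Z, dtype=float)
    u = np.asarray(u, dtype=float).ravel()
    if gamma.shape[1] != Z.shape[1]:
        raise ValueError(
            f"gamma columns {gamma.shape[1]} do not match Z columns {Z.shape[1]}"
        )
    if len(u) != Z.shape[0]:
        raise ValueError("u must have one entry per row of Z")
    lin = Z @ gamma.T  # (N, K-1)
    tau = np.empty_like(lin)
    tau[:, 0] = lin[:, 0] + sigma_u * u
    for k in range(1, lin.shape[1]):
        tau[:, k] = tau[:, k - 1] + np.exp(np.clip(lin[:, k], -EXP_CLIP, EXP_CLIP))
    return tau


def perception_scale(alpha, sigma_v, ystar, theta_j):
    """Heteroskedastic vignette perception sd ``s_ij``.

    ``s_ij = sigma_v * exp(alpha (y*_i - theta_j)^2)`` where
    ``y*_i = beta'x_i + eps_i``.  With ``alpha = 0`` this is constant at
    ``sigma_v`` (vignette equivalence); for ``alpha > 0`` it grows with
    the respondent-vignette distance, minimised at ``y*_i = theta_j``.
    Broadcasts over array arguments.
    """
    if sigma_v <= 0:
        raise ValueError("sigma_v must be positive")
    d = np.asarray(ystar, dtype=float) - np.asarray(theta_j, dtype=float)
    expo = np.clip(alpha * d * d, -EXP_CLIP, EXP_CLIP)
    return sigma_v * np.exp(expo)


def augment_cutoffs(tau: np.ndarray) -> np.ndarray:
    """Prepend -inf and append +inf columns to a cut-point matrix."""
    tau = np.atleast_2d(tau)
    n = tau.shape[0]
    return np.hstack([np.full((n, 1), -np.inf), tau, np.full((n, 1), np.inf)])


def self_report_indicator(y, tau, ystar):
    """Indicator that ``y*`` falls in the observed category's interval.

    Returns 1 iff ``tau^{y-1} <= y* < tau^y`` under the half-open
    interval convention (the boundary belongs to the category above).
    ``tau`` holds the finite cut-points (length ``K-1`` per respondent).
    """
    tau = np.atleast_2d(tau)
    y = np.asarray(y, dtype=np.int64).ravel()
    ystar = np.asarray(ystar, dtype=float).ravel()
    K = tau.shape[1] + 1
    if np.any((y < 1) | (y > K)):
        raise ValueError(f"categories must lie in 1..{K}")
    aug = augment_cutoffs(tau)
    rows = np.arange(len(y))
    lo = aug[rows, y - 1]
    hi = aug[rows, y]
    return ((lo <= ystar) & (ystar < hi)).astype(np.int64)


def vignette_category_prob(k, tau, theta_j, s):
    """``Pr(V_ij = k | u_i, eps_i)`` — conditional vignette cell probability.

    ``Phi((tau^k - theta_j)/s) - Phi((tau^{k-1} - theta_j)/s)`` with the
    usual ``+/-inf`` boundaries.  ``tau`` holds the finite cut-points.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("perception scale s must be positive")
    tau = np.atleast_2d(tau)
    k = np.asarray(k, dtype=np.int64).ravel()
    K = tau.shape[1] + 1
    if np.any((k < 1) | (k > K)):
        raise ValueError(f"categories must lie in 1..{K}")
    aug = augment_cutoffs(tau)
    rows = np.arange(aug.shape[0]) if k.shape[0] == aug.shape[0] else np.zeros(
        k.shape[0], dtype=int
    )
    hi = (aug[rows, k] - theta_j) / s
    lo = (aug[rows, k - 1] - theta_j) / s
    upper = np.where(np.isposinf(hi), 1.0, ndtr(np.where(np.isposinf(hi), 0.0, hi)))
    lower = np.where(np.isneginf(lo), 0.0, ndtr(np.where(np.isneginf(lo), 0.0, lo)))
    out = upper - lower
    return out if out.shape else float(out)


def expected_hetero_sd(alpha: float, sigma_v: float, mu_c, theta_j):
    """Expected heteroskedastic perception sd, integrating out ``eps``.

    Closed form of ``E_eps[ sigma_v exp(alpha (c + eps)^2) ]`` with
    ``c = beta'x_i - theta_j`` and ``eps ~ N(0,1)``:

        ``sigma_v (1 - 2 alpha)^{-1/2} exp(alpha c^2 / (1 - 2 alpha))``

    finite only for ``alpha < 1/2``.  Used to summarise the effective
    per-respondent, per-vignette noise level of a fitted model.
    """
    if alpha >= 0.5:
        raise ValueError(
            f"expected heteroskedastic sd diverges for alpha >= 0.5 (got {alpha})"
        )
    if sigma_v <= 0:
        raise ValueError("sigma_v must be positive")
    c = np.asarray(mu_c, dtype=float) - np.asarray(theta_j, dtype=float)
    one_m = 1.0 - 2.0 * alpha
    out = sigma_v / np.sqrt(one_m) * np.exp(
        np.clip(alpha * c * c / one_m, -EXP_CLIP, EXP_CLIP)
    )
    return out if out.shape else float(out)
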