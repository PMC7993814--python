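"""Maximum-likelihood fitting of ordered probit and HOPIT variants.

The optimizer works on an unconstrained re-parameterisation (sd
parameters on the log scale; the heteroskedasticity parameter alpha
bounded above by 0.49 so that the expected heteroskedastic sd stays
finite) with numeric gradients.  Standard errors come from the observed
information (inverse numerical Hessian at the optimum), delta-mapped to
the natural scale.

Model variants
--------------
``ordered_probit``   constant cut-points, no vignettes (exact likelihood)
``standard_hopit``   respondent-specific cut-points, homoskedastic
                     vignette perceptions (alpha fixed at 0)
``extended_hopit``   heteroskedastic vignette perceptions (alpha free)
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr
from scipy.stats import chi2

from .data import HopitParams, SurveyDataset
from .likelihood import QmcDraws, halton_points, total_loglik

logger = logging.getLogger(__name__)

VARIANTS = ("ordered_probit", "standard_hopit", "extended_hopit")


@dataclass
class FitConfig:
    """Numerical settings for a maximum-likelihood fit."""

    draws: tuple[int, int, int] = (200, 1000, 101)  # (R, skip, leap)
    gtol: float = 1e-5
    ftol: float = 1e-9
    maxiter: int = 500
    alpha_lower: float = -0.25
    alpha_upper: float = 0.49
    compute_se: bool = False
    hessian_step: float = 1e-4


@dataclass
class FitResult:
    """A fitted model: estimates, uncertainty, fit measures, diagnostics."""

    variant: str
    params: HopitParams | None
    beta: np.ndarray
    loglik: float
    aic: float
    n_params: int
    converged: bool
    n_iter: int
    n_fev: int
    draws_spec: tuple[int, int, int] | None
    param_names: list[str]
    estimates: np.ndarray  # natural-scale free parameters
    se: np.ndarray | None = None
    tstats: np.ndarray | None = None
    data_fingerprint: int = 0
    transformed: np.ndarray | None = None  # optimizer-scale optimum

    def summary_rows(self):
        """(name, estimate, se, t, stars) tuples for reporting."""
        rows = []
        for idx, name in enumerate(self.param_names):
            est = self.estimates[idx]
            se = self.se[idx] if self.se is not None else np.nan
            t = self.tstats[idx] if self.tstats is not None else np.nan
            p = 2 * (1 - ndtr(abs(t))) if np.isfinite(t) else np.nan
            stars = ""
            if np.isfinite(p):
                stars = "***" if p < 0.01 else "**" if p < 0.05 else "*" if p < 0.1 else ""
            rows.append((name, est, se, t, stars))
        return rows


@dataclass
class LrTestResult:
    """Likelihood-ratio test of the extended against the standard HOPIT."""

    statistic: float
    df: int
    p_value: float

    @property
    def reject_at_005(self) -> bool:
        return self.statistic > chi2.ppf(0.95, self.df)


# ---------------------------------------------------------------------------
# Ordered probit (exact likelihood; also the initializer's backbone)
# ---------------------------------------------------------------------------


def _op_nll(v: np.ndarray, y: np.ndarray, X: np.ndarray, K: int) -> float:
    p = X.shape[1]
    beta, c = v[:p], v[p:]
    tau = np.empty(K - 1)
    tau[0] = c[0]
    for k in range(1, K - 1):
        tau[k] = tau[k - 1] + np.exp(min(c[k], 700.0))
    xb = X @ beta
    aug = np.concatenate([[-np.inf], tau, [np.inf]])
    cell = ndtr(np.clip(aug[y] - xb, -40, 40)) - ndtr(np.clip(aug[y - 1] - xb, -40, 40))
    return -np.log(np.maximum(cell, 1e-300)).sum()


def fit_ordered_probit_raw(y: np.ndarray, X: np.ndarray, K: int):
    """Ordered probit with constant cut-points on arbitrary (y, X).

    Returns ``(beta, tau, result)`` where ``tau`` are the fitted
    constant thresholds.  Increments are parameterised on the log scale
    so thresholds are monotone by construction.
    """
    y = np.asarray(y, dtype=np.int64).ravel()
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = np.where(sd == 0)[0]
        raise ValueError(f"degenerate (zero-variance) X column(s): {bad.tolist()}")
    x0 = np.zeros(X.shape[1] + K - 1)
    # seed thresholds at the unconditional category split
    cum = np.clip(np.cumsum(np.bincount(y, minlength=K + 1)[1:K]) / len(y), 0.01, 0.99)
    from scipy.special import ndtri

    t0 = ndtri(cum)
    x0[X.shape[1]] = t0[0]
    for k in range(1, K - 1):
        x0[X.shape[1] + k] = np.log(max(t0[k] - t0[k - 1], 1e-2))
    res = minimize(
        _op_nll, x0, args=(y, X, K), method="L-BFGS-B", options=dict(maxiter=500)
    )
    p = X.shape[1]
    beta, c = res.x[:p], res.x[p:]
    tau = np.empty(K - 1)
    tau[0] = c[0]
    for k in range(1, K - 1):
        tau[k] = tau[k - 1] + np.exp(c[k])
    return beta, tau, res


# ---------------------------------------------------------------------------
# Parameter packing (optimizer scale <-> natural scale)
# ---------------------------------------------------------------------------


def _pack(params: HopitParams, extended: bool) -> np.ndarray:
    v = [params.beta, params.gamma.ravel(), params.theta,
         [np.log(params.sigma_u), np.log(params.sigma_v)]]
    if extended:
        v.append([params.alpha])
    return np.concatenate(v)


def _unpack(v: np.ndarray, p: int, q: int, K: int, J: int, extended: bool) -> HopitParams:
    n_g = (K - 1) * q
    beta = v[:p]
    gamma = v[p : p + n_g].reshape(K - 1, q)
    theta = v[p + n_g : p + n_g + J]
    lsu, lsv = v[p + n_g + J], v[p + n_g + J + 1]
    alpha = float(v[p + n_g + J + 2]) if extended else 0.0
    return HopitParams(
        beta=beta,
        gamma=gamma,
        theta=theta,
        sigma_u=float(np.exp(np.clip(lsu, -30, 30))),
        sigma_v=float(np.exp(np.clip(lsv, -30, 30))),
        alpha=alpha,
    )


def _natural_jacobian_diag(v: np.ndarray, p: int, q: int, K: int, J: int,
                           extended: bool) -> np.ndarray:
    """d(natural)/d(transformed): exp for the two log-sd entries, 1 elsewhere."""
    jac = np.ones_like(v)
    i_lsu = p + (K - 1) * q + J
    jac[i_lsu] = np.exp(v[i_lsu])
    jac[i_lsu + 1] = np.exp(v[i_lsu + 1])
    return jac


def _free_param_names(data: SurveyDataset, extended: bool) -> list[str]:
    names = [f"beta{i + 1}" for i in range(data.p)]
    for k in range(data.K - 1):
        names += [f"gamma{k + 1}_{j}" for j in range(data.q)]
    names += [f"theta{j + 1}" for j in range(data.J)]
    names += ["sigma_u", "sigma_v"]
    if extended:
        names.append("alpha")
    return names


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------


def initialize(data: SurveyDataset, variant: str = "extended_hopit") -> HopitParams:
    """Deterministic starting values for a HOPIT fit.

    An ordered probit with constant cut-points is fitted first.  Its
    thresholds seed the cut-point intercepts and log-increments.  A
    pooled ordered probit of the vignette ratings on the (non-intercept)
    cut-point covariates pins down the sign and rough scale of the
    threshold slopes, which cannot be recovered from the self-report
    alone when cut-point shifts track the outcome index; the outcome
    coefficients are then the self-report ordered probit slopes plus
    those threshold slopes.  Vignette locations start at the pooled
    category barycentre on the threshold scale; both sds start at 0.5
    and alpha at 0.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    K, J, p, q = data.K, data.J, data.p, data.q
    b_y, tau0, _ = fit_ordered_probit_raw(data.y, data.X, K)

    gamma = np.zeros((K - 1, q))
    icol = int(
        np.where(np.all(data.Z == data.Z[0:1], axis=0) & (data.Z[0] != 0))[0][0]
    )
    gamma[0, icol] = tau0[0] / data.Z[0, icol]
    for k in range(1, K - 1):
        gamma[k, icol] = np.log(max(tau0[k] - tau0[k - 1], 1e-2)) / data.Z[0, icol]

    beta = b_y.copy()
    if J > 0:
        # pooled vignette ordered probit: stack (V_ij, z_i, vignette dummies)
        zslice = np.delete(np.arange(q), icol)
        if len(zslice):
            Vl = data.V.T.ravel()
            Zs = np.tile(data.Z[:, zslice], (J, 1))
            D = np.repeat(np.eye(J), data.n, axis=0)[:, 1:] if J > 1 else np.empty(
                (data.n * J, 0)
            )
            try:
                bv, _, _ = fit_ordered_probit_raw(Vl, np.hstack([Zs, D]), K)
                g1_slopes = -bv[: len(zslice)]
                gamma[0, zslice] = g1_slopes
                # the self-report index identifies beta - gamma_1 slopes,
                # so add the slope estimate back for shared covariates
                bmap = _match_columns(data.X, data.Z[:, zslice])
                for xi, zi in bmap:
                    beta[xi] = b_y[xi] + g1_slopes[zi]
            except ValueError:
                pass

    theta = np.zeros(J)
    if J > 0:
        mids = np.empty(K)
        aug = np.concatenate([[tau0[0] - 2.0], tau0, [tau0[-1] + 2.0]])
        for k in range(K):
            mids[k] = 0.5 * (aug[k] + aug[k + 1])
        for j in range(J):
            freq = np.bincount(data.V[:, j], minlength=K + 1)[1:] / data.n
            theta[j] = freq @ mids

    return HopitParams(
        beta=beta, gamma=gamma, theta=theta, sigma_u=0.5, sigma_v=0.5, alpha=0.0
    )


def _match_columns(X: np.ndarray, Zs: np.ndarray) -> list[tuple[int, int]]:
    """Indices (xi, zi) of X columns appearing verbatim among Zs columns."""
    out = []
    for xi in range(X.shape[1]):
        for zi in range(Zs.shape[1]):
            if np.array_equal(X[:, xi], Zs[:, zi]):
                out.append((xi, zi))
                break
    return out


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def fit(
    data: SurveyDataset,
    variant: str = "extended_hopit",
    config: FitConfig | None = None,
    start: HopitParams | None = None,
    draws: QmcDraws | None = None,
) -> FitResult:
    """Maximum (simulated) likelihood fit of the requested variant.

    Deterministic given ``config`` and ``draws``: the Halton draws, the
    initialization and the optimizer are all non-random.  For nested
    comparisons (LR test), pass the *same* ``draws`` object to both
    fits so the statistic is not contaminated by integration noise.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    config = config or FitConfig()

    if variant == "ordered_probit":
        return _fit_ordered_probit(data, config)
    if data.J < 1:
        raise ValueError("HOPIT variants require at least one vignette")

    extended = variant == "extended_hopit"
    if draws is None:
        draws = halton_points(*config.draws)
    p, q, K, J = data.p, data.q, data.K, data.J
    if start is None:
        start = initialize(data, variant)
    x0 = _pack(start, extended)

    def nll(v: np.ndarray) -> float:
        params = _unpack(v, p, q, K, J, extended)
        return -total_loglik(params, data, draws).total

    bounds = [(None, None)] * len(x0)
    if extended:
        bounds[-1] = (config.alpha_lower, config.alpha_upper)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = minimize(
            nll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options=dict(
                maxiter=config.maxiter,
                maxfun=10**7,  # let maxiter, not the eval counter, bind
                ftol=config.ftol,
                gtol=config.gtol,
                maxcor=20,
            ),
        )
    params = _unpack(res.x, p, q, K, J, extended)
    names = _free_param_names(data, extended)
    estimates = np.concatenate(
        [
            params.beta,
            params.gamma.ravel(),
            params.theta,
            [params.sigma_u, params.sigma_v],
            [params.alpha] if extended else [],
        ]
    )
    n_params = len(estimates)
    loglik = -res.fun
    result = FitResult(
        variant=variant,
        params=params,
        beta=params.beta,
        loglik=float(loglik),
        aic=float(2 * n_params - 2 * loglik),
        n_params=n_params,
        converged=bool(res.success),
        n_iter=int(res.nit),
        n_fev=int(res.nfev),
        draws_spec=draws.spec(),
        param_names=names,
        estimates=estimates,
        data_fingerprint=data.fingerprint(),
        transformed=res.x.copy(),
    )
    if not res.success:
        logger.warning("fit(%s) did not converge: %s", variant, res.message)
    final_floored = total_loglik(params, data, draws).n_floored
    if final_floored:
        logger.warning(
            "fit(%s): %d respondent(s) at the likelihood floor at the optimum",
            variant,
            final_floored,
        )
    if config.compute_se:
        attach_standard_errors(result, data, config, draws)
    return result


def _fit_ordered_probit(data: SurveyDataset, config: FitConfig) -> FitResult:
    beta, tau, res = fit_ordered_probit_raw(data.y, data.X, data.K)
    names = [f"beta{i + 1}" for i in range(data.p)] + [
        f"tau{k + 1}" for k in range(data.K - 1)
    ]
    estimates = np.concatenate([beta, tau])
    n_params = len(estimates)
    loglik = -res.fun
    result = FitResult(
        variant="ordered_probit",
        params=None,
        beta=beta,
        loglik=float(loglik),
        aic=float(2 * n_params - 2 * loglik),
        n_params=n_params,
        converged=bool(res.success),
        n_iter=int(res.nit),
        n_fev=int(res.nfev),
        draws_spec=None,
        param_names=names,
        estimates=estimates,
        data_fingerprint=data.fingerprint(),
        transformed=res.x.copy(),
    )
    if config.compute_se:
        attach_standard_errors(result, data, config, None)
    return result


def fit_nested_pair(
    data: SurveyDataset,
    config: FitConfig | None = None,
    draws: QmcDraws | None = None,
) -> tuple[FitResult, FitResult]:
    """Fit the standard and extended HOPIT as a properly nested pair.

    Protocol: fit the standard model from the deterministic
    initialization; fit the extended model warm-started from the
    standard optimum; then *re-polish* the standard model warm-started
    from the extended optimum with alpha dropped, keeping the better of
    the two standard solutions. Without the polish step, a standard fit
    that stops slightly short of its optimum inflates the LR statistic
    and lets the extended fit misattribute the shortfall to alpha. If
    the polish improves the standard log-likelihood materially, the
    extended fit is re-run once from the polished optimum.

    Returns ``(standard_fit, extended_fit)`` sharing ``draws``.
    """
    config = config or FitConfig()
    if draws is None:
        draws = halton_points(*config.draws)
    std = fit(data, "standard_hopit", config, draws=draws)
    ext = fit(data, "extended_hopit", config, start=std.params, draws=draws)
    for _ in range(2):
        polish = fit(data, "standard_hopit", config, start=ext.params, draws=draws)
        if polish.loglik <= std.loglik + 1e-9:
            break
        improved_by = polish.loglik - std.loglik
        std = polish
        if improved_by <= 0.1:
            break
        ext2 = fit(data, "extended_hopit", config, start=std.params, draws=draws)
        if ext2.loglik > ext.loglik:
            ext = ext2
        else:
            break
    return std, ext


# ---------------------------------------------------------------------------
# Standard errors
# ---------------------------------------------------------------------------


def _numeric_hessian(f, x: np.ndarray, step: float) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    n = len(x)
    h = step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        e = np.zeros(n)
        e[i] = h[i]
        fp[i] = f(x + e)
        fm[i] = f(x - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(x + ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (
                fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm
            ) / (2 * h[i] * h[j])
    return H


def standard_errors(
    result: FitResult,
    data: SurveyDataset,
    config: FitConfig | None = None,
    draws: QmcDraws | None = None,
) -> np.ndarray:
    """Observed-information standard errors on the natural scale.

    Inverts the numerical Hessian of the negative log-likelihood at the
    optimum (computed on the transformed scale) and delta-maps the
    log-sd entries back.  A non-positive-definite Hessian is repaired by
    clipping its eigenvalues, with a warning.
    """
    config = config or FitConfig()
    x = result.transformed
    if x is None:
        raise ValueError("fit result carries no optimizer-scale optimum")
    if result.variant == "ordered_probit":

        def f(v):
            return _op_nll(v, data.y, data.X, data.K)

        jac = np.ones_like(x)
        # thresholds beyond the first are log-increment parameterised
        # on the optimizer scale; map to natural tau via chain rule
        p = data.p
        H = _numeric_hessian(f, x, config.hessian_step)
        cov_t = _safe_inverse(H)
        T = np.eye(len(x))
        for k in range(1, data.K - 1):
            # tau_k = tau_{k-1} + exp(c_k): accumulate
            T[p + k, p + 1 : p + k + 1] = [
                np.exp(x[p + i]) for i in range(1, k + 1)
            ]
            T[p + k, p] = 1.0
        cov_n = T @ cov_t @ T.T
        se = np.sqrt(np.maximum(np.diag(cov_n), 0.0))
        return se

    if draws is None:
        draws = halton_points(*(result.draws_spec or config.draws))
    extended = result.variant == "extended_hopit"
    p, q, K, J = data.p, data.q, data.K, data.J

    def f(v):
        return -total_loglik(_unpack(v, p, q, K, J, extended), data, draws).total

    H = _numeric_hessian(f, x, config.hessian_step)
    cov_t = _safe_inverse(H)
    jac = _natural_jacobian_diag(x, p, q, K, J, extended)
    cov_n = cov_t * np.outer(jac, jac)
    return np.sqrt(np.maximum(np.diag(cov_n), 0.0))


def _safe_inverse(H: np.ndarray) -> np.ndarray:
    try:
        eig = np.linalg.eigvalsh(H)
        if eig.min() <= 0:
            logger.warning(
                "Hessian not positive definite (min eig %.3g); clipping", eig.min()
            )
            w, Q = np.linalg.eigh(H)
            w = np.maximum(w, 1e-8 * max(w.max(), 1.0))
            H = Q @ np.diag(w) @ Q.T
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        logger.warning("singular Hessian; standard errors unavailable")
        return np.full_like(H, np.nan)


def attach_standard_errors(
    result: FitResult,
    data: SurveyDataset,
    config: FitConfig | None = None,
    draws: QmcDraws | None = None,
) -> FitResult:
    se = standard_errors(result, data, config, draws)
    result.se = se
    with np.errstate(divide="ignore", invalid="ignore"):
        result.tstats = np.where(se > 0, result.estimates / se, np.nan)
    return result


# ---------------------------------------------------------------------------
# LR test
# ---------------------------------------------------------------------------


def lr_test(fit_extended: FitResult, fit_standard: FitResult) -> LrTestResult:
    """LR test of the extended HOPIT (full) against the standard HOPIT (reduced).

    ``statistic = -2 (L_std - L_ext)``, one degree of freedom (alpha),
    upper-tail chi-square p-value.  Both fits must come from the same
    dataset and share the same integration draws; a slightly negative
    statistic (integration noise at the shared-draw level) is clamped
    to zero with a warning.
    """
    if fit_extended.variant != "extended_hopit" or fit_standard.variant != "standard_hopit":
        raise ValueError("lr_test expects (extended_hopit, standard_hopit) fits")
    if fit_extended.data_fingerprint != fit_standard.data_fingerprint:
        raise ValueError("fits were not produced from the same dataset")
    if fit_extended.draws_spec != fit_standard.draws_spec:
        raise ValueError("fits do not share the same integration draws")
    stat = -2.0 * (fit_standard.loglik - fit_extended.loglik)
    if stat < 0:
        logger.warning("negative LR statistic %.3g clamped to 0", stat)
        stat = 0.0
    return LrTestResult(statistic=float(stat), df=1, p_value=float(chi2.sf(stat, 1)))
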