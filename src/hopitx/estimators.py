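"""Scikit-learn style estimators for vignette-anchored ordinal models.

These wrap the maximum-likelihood machinery in :mod:`hopitx.estimation`
behind the familiar ``fit`` / ``predict`` / ``get_params`` surface so
that model selection utilities and pipelines compose with them.  The
ordinal self-report is the target ``y``; vignette ratings and cut-point
covariates are passed as fit keyword arguments, mirroring how survey
weights travel in other estimators.

Example
-------
>>> est = ExtendedHopit(R=200)
>>> est.fit(X, y, vignettes=V, Z=Z)
>>> est.alpha_, est.loglik_
>>> est.predict(X, Z=Z)
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .data import SurveyDataset
from .estimation import FitConfig, attach_standard_errors
from .estimation import fit as _fit
from .estimation import lr_test as _lr_test
from .evaluation import predict_outcome, predict_outcome_proba
from .likelihood import halton_points


class _BaseHopit(BaseEstimator):
    """Shared plumbing of the HOPIT-family estimators."""

    _variant: str = ""

    def __init__(
        self,
        R: int = 200,
        skip: int = 1000,
        leap: int = 101,
        gtol: float = 1e-5,
        ftol: float = 1e-9,
        maxiter: int = 500,
        compute_se: bool = False,
    ):
        self.R = R
        self.skip = skip
        self.leap = leap
        self.gtol = gtol
        self.ftol = ftol
        self.maxiter = maxiter
        self.compute_se = compute_se

    def _config(self) -> FitConfig:
        return FitConfig(
            draws=(self.R, self.skip, self.leap),
            gtol=self.gtol,
            ftol=self.ftol,
            maxiter=self.maxiter,
            compute_se=False,  # deferred; see fit()
        )

    def _dataset(self, X, y, vignettes, Z, K) -> SurveyDataset:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=np.int64).ravel()
        if vignettes is None:
            vignettes = np.empty((len(y), 0), dtype=np.int64)
        V = np.atleast_2d(np.asarray(vignettes, dtype=np.int64))
        if V.shape[0] != len(y) and V.shape[1] == len(y):
            V = V.T
        if Z is None:
            Z = np.hstack([np.ones((len(y), 1)), X])
        if K is None:
            K = int(max(y.max(), V.max() if V.size else 0))
        return SurveyDataset(y=y, V=V, X=X, Z=np.asarray(Z, dtype=float), K=K)

    def fit(self, X, y, vignettes=None, Z=None, K=None, start=None):
        """Fit by simulated maximum likelihood.

        Parameters
        ----------
        X : (N, p) outcome covariates (no intercept column).
        y : (N,) ordinal self-report coded 1..K.
        vignettes : (N, J) ordinal vignette ratings, required for the
            HOPIT variants.
        Z : (N, q) cut-point covariates including an intercept column;
            defaults to ``[1 | X]``.
        K : number of categories; inferred from the data if omitted.
        start : optional HopitParams warm start.
        """
        data = self._dataset(X, y, vignettes, Z, K)
        config = self._config()
        draws = (
            halton_points(*config.draws) if self._variant != "ordered_probit" else None
        )
        res = _fit(data, self._variant, config, start=start, draws=draws)
        if self.compute_se:
            attach_standard_errors(res, data, config, draws)
        self.result_ = res
        self.draws_ = draws
        self.coef_ = res.beta.copy()
        self.loglik_ = res.loglik
        self.aic_ = res.aic
        self.converged_ = res.converged
        self.n_iter_ = res.n_iter
        self.se_ = res.se
        self.tstats_ = res.tstats
        self.n_features_in_ = data.p
        if res.params is not None:
            self.cutpoint_coefs_ = res.params.gamma.copy()
            self.vignette_locations_ = res.params.theta.copy()
            self.sigma_u_ = res.params.sigma_u
            self.sigma_v_ = res.params.sigma_v
            self.alpha_ = res.params.alpha
        return self

    def predict(self, X, Z=None):
        """Modal predicted ordinal category (ties toward the lower one)."""
        check_is_fitted(self, "result_")
        data = self._predict_dataset(X, Z)
        draws = self.draws_ or halton_points(*self._config().draws)
        return predict_outcome(self.result_, data, draws)

    def predict_proba(self, X, Z=None):
        """Marginal category probabilities ``Pr(y = k | x, z)``, shape (N, K)."""
        check_is_fitted(self, "result_")
        data = self._predict_dataset(X, Z)
        draws = self.draws_ or halton_points(*self._config().draws)
        return predict_outcome_proba(self.result_, data, draws)

    def predict_latent(self, X):
        """Fitted latent index ``beta_hat'x``."""
        check_is_fitted(self, "result_")
        return np.asarray(X, dtype=float) @ self.coef_

    def _predict_dataset(self, X, Z):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if Z is None:
            Z = np.hstack([np.ones((n, 1)), X])
        K = (
            self.result_.params.K
            if self.result_.params is not None
            else len(self.result_.estimates) - self.n_features_in_ + 1
        )
        dummy_y = np.ones(n, dtype=np.int64)
        return SurveyDataset(
            y=dummy_y, V=np.empty((n, 0), dtype=np.int64), X=X,
            Z=np.asarray(Z, dtype=float), K=K,
        )

    def score(self, X=None, y=None):
        """Fitted log-likelihood (the training objective)."""
        check_is_fitted(self, "result_")
        return self.loglik_


class OrderedProbit(_BaseHopit):
    """Ordered probit with constant cut-points (no vignettes).

    The degenerate member of the family: exact likelihood, no
    integration.  Serves as the initializer backbone and as a baseline.
    """

    _variant = "ordered_probit"


class StandardHopit(_BaseHopit):
    """Hierarchical ordered probit with homoskedastic vignette perceptions.

    Respondent-specific cut-points identified through anchoring
    vignettes under vignette equivalence (``alpha = 0``).
    """

    _variant = "standard_hopit"


class ExtendedHopit(_BaseHopit):
    """HOPIT with heteroskedastic vignette perceptions.

    Perception noise for a respondent-vignette pair scales as
    ``sigma_v exp(alpha (y* - theta_j)^2)``; ``alpha`` is estimated and
    the fitted model nests :class:`StandardHopit` at ``alpha = 0``.
    """

    _variant = "extended_hopit"


def lr_test_estimators(extended: ExtendedHopit, standard: StandardHopit):
    """LR test from two fitted estimators sharing data and draws."""
    check_is_fitted(extended, "result_")
    check_is_fitted(standard, "result_")
    return _lr_test(extended.result_, standard.result_)
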