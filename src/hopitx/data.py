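"""Core data containers for vignette-anchored ordinal survey data.

The two central objects are :class:`SurveyDataset` — one ordinal
self-assessment plus ``J`` ordinal vignette ratings per respondent,
together with outcome covariates ``X`` and cut-point covariates ``Z`` —
and :class:`HopitParams`, the full parameter set of the (extended)
hierarchical ordered probit model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _as_2d_float(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


@dataclass
class SurveyDataset:
    """Respondent-level survey data for HOPIT-type models.

    Parameters
    ----------
    y : (N,) int array
        Ordinal self-assessment, coded ``1..K``.
    V : (N, J) int array
        Ordinal vignette ratings, coded ``1..K``.  ``J`` may be 0.
    X : (N, p) float array
        Outcome-equation covariates.  No intercept column: the outcome
        intercept is fixed at zero for identification.
    Z : (N, q) float array
        Cut-point-equation covariates.  Must include an explicit
        intercept column (the first threshold equation needs a level).
    K : int
        Number of response categories (>= 2).
    """

    y: np.ndarray
    V: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int64).ravel()
        self.V = np.asarray(self.V, dtype=np.int64)
        if self.V.ndim == 1:
            self.V = self.V.reshape(len(self.V), -1)
        self.X = _as_2d_float(self.X, "X")
        self.Z = _as_2d_float(self.Z, "Z")
        n = len(self.y)
        if self.V.shape[0] != n or self.X.shape[0] != n or self.Z.shape[0] != n:
            raise ValueError(
                "y, V, X, Z must share the number of rows; got "
                f"{n}, {self.V.shape[0]}, {self.X.shape[0]}, {self.Z.shape[0]}"
            )
        if self.K < 2:
            raise ValueError("K must be at least 2")
        for name, arr in (("y", self.y), ("V", self.V)):
            if arr.size and (arr.min() < 1 or arr.max() > self.K):
                raise ValueError(f"{name} entries must lie in 1..{self.K}")
        if not np.any(np.all(self.Z == self.Z[0:1], axis=0) & (self.Z[0] != 0)):
            raise ValueError(
                "Z must contain an explicit (constant, nonzero) intercept column"
            )

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def J(self) -> int:
        return self.V.shape[1]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    def fingerprint(self) -> int:
        """Cheap content hash used to guard nested-model comparisons."""
        h = 0
        for a in (self.y, self.V.ravel(), self.X.ravel(), self.Z.ravel()):
            h ^= hash(a.tobytes())
        return h ^ hash((self.K,))


@dataclass
class HopitParams:
    """Parameters of the (extended) hierarchical ordered probit.

    ``beta`` enters the latent outcome ``y* = beta'x + eps`` with
    ``eps ~ N(0,1)``; ``gamma`` (one row per threshold, ``K-1`` rows)
    defines respondent-specific cut-points; ``theta`` are vignette
    locations; ``sigma_u`` the cut-point shift sd; ``sigma_v`` the
    baseline vignette perception sd; ``alpha`` scales perception noise
    with squared respondent-vignette distance.  ``alpha = 0`` recovers
    the standard HOPIT.  Identification fixes the outcome intercept at 0
    and the outcome error sd at 1; neither is stored.
    """

    beta: np.ndarray
    gamma: np.ndarray
    theta: np.ndarray
    sigma_u: float
    sigma_v: float
    alpha: float = 0.0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        self.theta = np.asarray(self.theta, dtype=float).ravel()
        self.sigma_u = float(self.sigma_u)
        self.sigma_v = float(self.sigma_v)
        self.alpha = float(self.alpha)
        if self.sigma_u <= 0 or self.sigma_v <= 0:
            raise ValueError("sigma_u and sigma_v must be positive")

    @property
    def K(self) -> int:
        return self.gamma.shape[0] + 1

    @property
    def J(self) -> int:
        return len(self.theta)

    def flat(self) -> np.ndarray:
        """Natural-scale flat vector: beta, gamma rows, theta, sigma_u, sigma_v, alpha."""
        return np.concatenate(
            [self.beta, self.gamma.ravel(), self.theta,
             [self.sigma_u, self.sigma_v, self.alpha]]
        )

    def names(self) -> list[str]:
        out = [f"beta{i + 1}" for i in range(len(self.beta))]
        for k in range(self.gamma.shape[0]):
            out += [f"gamma{k + 1}_{j}" for j in range(self.gamma.shape[1])]
        out += [f"theta{j + 1}" for j in range(len(self.theta))]
        out += ["sigma_u", "sigma_v", "alpha"]
        return out
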