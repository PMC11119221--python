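"""Maximum-likelihood fitting of one candidate model.

Fixed-effects-only candidates are ordinary least squares with the ML
residual-variance divisor ``RSS/N``, giving the closed-form log-likelihood
``-(N/2)(ln(2π σ̂²) + 1)``.

Mixed candidates maximize the Gaussian marginal likelihood

    LL = -1/2 Σ_g [ n_g ln(2π) + ln|V_g| + r_g' V_g^{-1} r_g ],
    V_g = Z_g Ψ Z_g' + σ² I,   r_g = y_g - X_g β,

with an unstructured (correlated) q×q random-effect covariance Ψ.  β and σ²
are profiled out analytically; the optimizer works on the lower-triangular
relative-covariance factor Λ (Ψ = σ² Λ Λ', diagonal ≥ 0), so only
q(q+1)/2 parameters are searched.  With W_g = I + Z_g Λ Λ' Z_g' the
profiled deviance is

    d(Λ) = N ln(2π σ̂²(Λ)) + Σ_g ln|W_g| + N,

where β̂(Λ) is generalized least squares and σ̂²(Λ) = Σ r'W⁻¹r / N.  All
per-group quantities reduce, via the Woodbury identity, to q×q solves on
precomputed cross-products, so one deviance evaluation is cheap regardless
of group sizes.

Information criteria follow the standard penalized forms
AIC = -2LL + 2k and BIC = -2LL + k·ln(N), with k counting fixed
coefficients (after categorical expansion, intercept included), the
q(q+1)/2 free covariance parameters, and the residual variance.

Estimation is ML, not REML: the exploration sweep compares models with
different fixed effects, and REML likelihoods are not comparable across
fixed-effect structures.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .formula import ModelFormula

__all__ = [
    "FitError",
    "FitResult",
    "OptimizerSettings",
    "build_design",
    "fit_model",
    "fit_fixed_only",
    "fit_lmm",
    "information_criteria",
    "listwise_complete",
]


class FitError(ValueError):
    """Raised for degenerate design matrices or unusable data."""


@dataclass(frozen=True)
class OptimizerSettings:
    """Convergence controls for the profiled-deviance optimizer.

    ``tol`` is the relative-deviance convergence tolerance, ``max_iter``
    the L-BFGS-B iteration cap, ``boundary_tol`` the Λ-diagonal threshold
    below which a variance component is flagged singular, and
    ``start_diag`` the deterministic starting value for the Λ diagonal.
    """

    tol: float = 1e-8
    max_iter: int = 500
    boundary_tol: float = 1e-4
    start_diag: float = 0.5


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit summary for one candidate model."""

    model: ModelFormula
    loglik: float
    n_params: int
    n_obs: int
    aic: float
    bic: float
    converged: bool
    singular: bool
    message: str = ""
    beta: np.ndarray | None = None
    sigma2: float | None = None
    psi: np.ndarray | None = None
    fixed_names: tuple[str, ...] = ()


def information_criteria(
    loglik: float, n_params: int, n_obs: int
) -> tuple[float, float]:
    """Standard AIC and BIC from a maximized log-likelihood.

    AIC = -2·LL + 2k,  BIC = -2·LL + k·ln(N).  A non-finite log-likelihood
    yields NaN criteria rather than an error, so failed fits stay rankable
    (last).
    """
    if n_params < 1:
        raise ValueError("n_params must be >= 1")
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    if not math.isfinite(loglik):
        return math.nan, math.nan
    aic = -2.0 * loglik + 2.0 * n_params
    bic = -2.0 * loglik + n_params * math.log(n_obs)
    return aic, bic


def listwise_complete(data: pd.DataFrame, full: ModelFormula) -> pd.DataFrame:
    """Drop rows with missingness in any column of the *full* model.

    Done once, before exploration, so every candidate is fit on identical
    rows; information criteria are otherwise incomparable across candidates.
    """
    missing = [c for c in full.columns if c not in data.columns]
    if missing:
        raise FitError(f"data is missing model column(s): {missing}")
    out = data.dropna(subset=list(full.columns)).reset_index(drop=True)
    if out.empty:
        raise FitError("no complete rows remain after listwise deletion")
    return out


def _encode_column(col: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Numeric column as-is; categorical by treatment coding.

    Reference level is the first in sorted order; a categorical with L
    levels contributes L-1 indicator columns.
    """
    if pd.api.types.is_numeric_dtype(col) and not isinstance(
        col.dtype, pd.CategoricalDtype
    ):
        return col.to_numpy(dtype=float)[:, None], [col.name]
    levels = sorted(pd.unique(col.astype(str)))
    if len(levels) < 2:
        raise FitError(f"categorical column {col.name!r} has a single level")
    cols = [(col.astype(str) == lev).to_numpy(float) for lev in levels[1:]]
    names = [f"{col.name}[{lev}]" for lev in levels[1:]]
    return np.column_stack(cols), names


def build_design(
    m: ModelFormula, data: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None, np.ndarray | None, list[str]]:
    """Assemble y, X (with leading intercept), Z, and group codes.

    Returns ``(y, X, Z, groups, fixed_names)``; ``Z`` and ``groups`` are
    ``None`` for fixed-effects-only models.  Random-slope columns in Z must
    be numeric (slope candidates are continuous predictors by construction).
    """
    y = data[m.response].to_numpy(dtype=float)
    blocks = [np.ones((len(data), 1))]
    names = ["(Intercept)"]
    for term in m.fixed_terms:
        enc, enc_names = _encode_column(data[term])
        blocks.append(enc)
        names.extend(enc_names)
    X = np.hstack(blocks)
    if X.shape[0] <= X.shape[1]:
        raise FitError(
            f"not enough observations ({X.shape[0]}) for {X.shape[1]} coefficients"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("design matrix is rank deficient after encoding")
    if m.q == 0:
        return y, X, None, None, names
    zcols = [np.ones(len(data))]
    for term in m.random_slopes:
        if not pd.api.types.is_numeric_dtype(data[term]):
            raise FitError(f"random slope {term!r} must be numeric")
        zcols.append(data[term].to_numpy(dtype=float))
    Z = np.column_stack(zcols)
    groups = pd.factorize(data[m.group], sort=True)[0]
    return y, X, Z, groups, names


def _n_params(p: int, q: int) -> int:
    return p + q * (q + 1) // 2 + 1


def fit_fixed_only(m: ModelFormula, data: pd.DataFrame) -> FitResult:
    """OLS maximum-likelihood fit for a candidate with no random part."""
    if m.q != 0:
        raise ValueError("model has a random part; use fit_lmm")
    y, X, _, _, names = build_design(m, data)
    n = len(y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    if not math.isfinite(sigma2) or sigma2 <= 1e-12 * max(float(np.var(y)), 1e-30):
        raise FitError("zero residual variance (perfect fit): likelihood unbounded")
    loglik = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    k = _n_params(X.shape[1], 0)
    aic, bic = information_criteria(loglik, k, n)
    return FitResult(
        model=m, loglik=loglik, n_params=k, n_obs=n, aic=aic, bic=bic,
        converged=True, singular=False, beta=beta, sigma2=sigma2,
        psi=None, fixed_names=tuple(names),
    )


class _ProfiledDeviance:
    """Profiled deviance of the marginal likelihood over Λ.

    Precomputes per-group cross-products so each evaluation costs a q×q
    Cholesky per group plus one p×p solve overall.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, Z: np.ndarray, groups: np.ndarray):
        self.n, self.p = X.shape
        self.q = Z.shape[1]
        self.parts = []
        for g in np.unique(groups):
            idx = groups == g
            Xg, Zg, yg = X[idx], Z[idx], y[idx]
            self.parts.append(
                (Zg.T @ Zg, Zg.T @ Xg, Zg.T @ yg, Xg.T @ Xg, Xg.T @ yg, float(yg @ yg))
            )
        if len(self.parts) < 2:
            raise FitError("random effects require at least two groups")
        sizes = np.bincount(groups)
        if (sizes < self.q).any():
            warnings.warn(
                "some groups have fewer observations than the random-effect "
                "dimension; variance components may be poorly identified",
                stacklevel=3,
            )

    def lam(self, theta: np.ndarray) -> np.ndarray:
        L = np.zeros((self.q, self.q))
        L[np.tril_indices(self.q)] = theta
        return L

    def components(self, theta: np.ndarray):
        """Return (deviance, beta_hat, sigma2_hat, logdet_sum) at Λ(θ)."""
        L = self.lam(theta)
        q, p = self.q, self.p
        xtwx = np.zeros((p, p))
        xtwy = np.zeros(p)
        ytwy = 0.0
        logdet = 0.0
        eye = np.eye(q)
        for ztz, ztx, zty, xtx, xty, yty in self.parts:
            A = eye + L.T @ ztz @ L  # I + Λ'Z'ZΛ
            cA = np.linalg.cholesky(A)
            logdet += 2.0 * float(np.log(np.diag(cA)).sum())
            # Woodbury: W⁻¹ = I − ZΛ A⁻¹ Λ'Z'
            u_x = np.linalg.solve(cA, L.T @ ztx)   # cA⁻¹ Λ'Z'X
            u_y = np.linalg.solve(cA, L.T @ zty)
            xtwx += xtx - u_x.T @ u_x
            xtwy += xty - u_x.T @ u_y
            ytwy += yty - float(u_y @ u_y)
        beta = np.linalg.solve(xtwx, xtwy)
        rwr = ytwy - float(beta @ xtwy)
        sigma2 = max(rwr / self.n, 1e-300)
        dev = self.n * math.log(2 * math.pi * sigma2) + logdet + self.n
        return dev, beta, sigma2, logdet

    def __call__(self, theta: np.ndarray) -> float:
        try:
            return self.components(theta)[0]
        except np.linalg.LinAlgError:
            return math.inf


def fit_lmm(
    m: ModelFormula,
    data: pd.DataFrame,
    opts: OptimizerSettings | None = None,
) -> FitResult:
    """Profiled-ML fit for a candidate with a random part.

    Non-convergence is reported in the result (``converged=False``), not
    raised: during an exhaustive sweep a failed candidate must not abort
    the exploration.  ``singular=True`` flags a boundary solution (some
    random-effect variance effectively zero).
    """
    if m.q == 0:
        raise ValueError("model has no random part; use fit_fixed_only")
    opts = opts or OptimizerSettings()
    y, X, Z, groups, names = build_design(m, data)
    n = len(y)
    prof = _ProfiledDeviance(y, X, Z, groups)
    q = m.q
    n_theta = q * (q + 1) // 2
    theta0 = np.zeros(n_theta)
    diag_idx = np.cumsum(np.arange(1, q + 1)) - 1  # diagonal positions in tril order
    theta0[diag_idx] = opts.start_diag
    bounds = [(None, None)] * n_theta
    for i in diag_idx:
        bounds[i] = (0.0, None)

    res = optimize.minimize(
        prof,
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        options={
            "maxiter": opts.max_iter,
            "ftol": opts.tol,
            "gtol": 1e-7,
        },
    )
    dev, beta, sigma2, _ = prof.components(res.x)
    loglik = -0.5 * dev
    L = prof.lam(res.x)
    psi = sigma2 * (L @ L.T)
    singular = bool((np.abs(np.diag(L)) < opts.boundary_tol).any())
    k = _n_params(X.shape[1], q)
    aic, bic = information_criteria(loglik, k, n)
    return FitResult(
        model=m, loglik=loglik, n_params=k, n_obs=n, aic=aic, bic=bic,
        converged=bool(res.success), singular=singular,
        message=str(res.message), beta=beta, sigma2=sigma2, psi=psi,
        fixed_names=tuple(names),
    )


def fit_model(
    m: ModelFormula,
    data: pd.DataFrame,
    opts: OptimizerSettings | None = None,
) -> FitResult:
    """Dispatch to the OLS or mixed-model fitter by the model's random part."""
    if m.q == 0:
        return fit_fixed_only(m, data)
    return fit_lmm(m, data, opts)
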