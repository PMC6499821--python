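"""Maximum-likelihood GLS with a compound spatial-phylogenetic correlation.

The regression model is ``y = X b + e`` with ``e ~ N(0, sigma^2 C)`` and

    C = (1 - alpha) I + alpha [ beta P + (1 - beta) D ],

where ``P`` is the PhyloSor phylogenetic similarity matrix between grid
cells, ``D = exp(-(d / gamma)^2)`` the Gaussian decay of great-circle
centroid distance ``d``, ``alpha`` the share of spatial-plus-phylogenetic
structure in the residual, and ``beta`` the spatial-versus-phylogenetic
split.  Whatever ``(alpha, beta, gamma)``, ``C`` has unit diagonal.

Fitting profiles ``b`` and ``sigma^2`` out of the Gaussian likelihood and
minimises the profiled negative log-likelihood over ``(alpha, beta,
log gamma)`` with a bounded derivative-free simplex search from multiple
starts.  ML (not REML) is used throughout so that likelihood-ratio tests
across fixed-effect structures are valid.  All solves go through Cholesky
factorizations — never an explicit inverse — with a small ridge and an
eigenvalue-clamping repair as fallbacks before a singularity error
(advising heavier subsampling) is raised.

Predicted R^2 is leave-one-out and conditional: under GLS the prediction
for cell i borrows the correlated residuals of the other cells,

    yhat_i = x_i b + C[i, -i] C[-i, -i]^{-1} (y_{-i} - X_{-i} b),

computed for all i at once from the precision matrix.  With ``C = I`` the
conditional term vanishes and the measure reduces to the classical
in-sample R^2, so the GLS-minus-OLS difference isolates what spatial and
phylogenetic structure contributes.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

from .similarity import ensure_unit_diag_pd, gaussian_decay

__all__ = [
    "CorrelationParams",
    "GLSConfig",
    "FitResult",
    "LRResult",
    "ResidualReport",
    "SingularCorrelationError",
    "build_correlation",
    "negloglik",
    "fit_gls",
    "fit_gls_fixed",
    "fit_ols",
    "lr_test",
    "predicted_r2",
    "standardized_residuals",
]


class SingularCorrelationError(np.linalg.LinAlgError):
    pass


@dataclass(frozen=True)
class CorrelationParams:
    """(alpha, beta, gamma) of the residual correlation structure.

    alpha in [0, 1]: spatial+phylogenetic share of residual variance;
    beta in [0, 1]: spatial (1-beta) versus phylogenetic (beta) split;
    gamma_km > 0: Gaussian distance-decay range in km.
    """

    alpha: float
    beta: float
    gamma_km: float

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha={self.alpha} outside [0, 1]")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError(f"beta={self.beta} outside [0, 1]")
        if not self.gamma_km > 0:
            raise ValueError(f"gamma_km={self.gamma_km} must be > 0")


@dataclass(frozen=True)
class GLSConfig:
    """Optimizer settings for :func:`fit_gls`.

    Starts form a grid alpha, beta in {0.2, 0.5, 0.8} and gamma in
    {0.5, 1, 2} x median off-diagonal distance; the ``n_starts`` most
    promising grid points (by objective value) seed local searches, with a
    seeded jitter so restarts are reproducible.  gamma is searched on the
    log scale within [gamma_min, gamma_max_factor x max distance].
    """

    n_starts: int = 5
    alpha_starts: tuple[float, ...] = (0.2, 0.5, 0.8)
    beta_starts: tuple[float, ...] = (0.2, 0.5, 0.8)
    gamma_factors: tuple[float, ...] = (0.5, 1.0, 2.0)
    gamma_min: float = 1.0
    gamma_max_factor: float = 5.0
    ftol: float = 1e-8
    xtol: float = 1e-8
    maxiter: int = 4000
    seed: int = 0
    jitter: float = 0.05


@dataclass
class FitResult:
    """Fitted regression: coefficients, tests, ML correlation parameters."""

    method: str
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    sigma2: float
    params: CorrelationParams | None
    loglik: float
    n: int
    predicted_r2: float | None = None
    optimizer: dict | None = None

    @property
    def n_fixed(self) -> int:
        return len(self.names)

    def summary_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "t": self.t, "p": self.p},
            index=self.names,
        )

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "n": int(self.n),
            "loglik": float(self.loglik),
            "sigma2": float(self.sigma2),
            "predicted_r2": None
            if self.predicted_r2 is None
            else float(self.predicted_r2),
            "coefficients": {
                name: {
                    "coef": float(b),
                    "se": float(s),
                    "t": float(t),
                    "p": float(p),
                }
                for name, b, s, t, p in zip(
                    self.names, self.coef, self.se, self.t, self.p
                )
            },
        }
        if self.params is not None:
            d["correlation"] = {
                "alpha": self.params.alpha,
                "beta": self.params.beta,
                "gamma_km": self.params.gamma_km,
            }
        return d


@dataclass
class LRResult:
    """Likelihood-ratio test of nested fixed-effect structures."""

    lr: float
    df: int
    p: float

    def to_dict(self) -> dict:
        return {"lr": float(self.lr), "df": int(self.df), "p": float(self.p)}


@dataclass
class ResidualReport:
    standardized: np.ndarray  # raw residuals / sigma-hat (C has unit diagonal)
    whitened: np.ndarray  # L^-1 r / sigma-hat, iid N(0,1) under the model
    flags: np.ndarray  # |standardized| >= 1.96
    shapiro_p: float  # Shapiro-Wilk normality p on the whitened residuals


# -- correlation matrix and likelihood --------------------------------------


def build_correlation(
    params: CorrelationParams, P: np.ndarray, d: np.ndarray
) -> np.ndarray:
    """C = (1 - alpha) I + alpha [beta P + (1 - beta) exp(-(d/gamma)^2)]."""
    P = np.asarray(P, dtype=float)
    d = np.asarray(d, dtype=float)
    if P.shape != d.shape or P.shape[0] != P.shape[1]:
        raise ValueError("P and d must be square matrices of equal shape")
    n = P.shape[0]
    D = gaussian_decay(d, params.gamma_km)
    C = params.alpha * (params.beta * P + (1.0 - params.beta) * D)
    C[np.diag_indices(n)] = 0.0
    C = 0.5 * (C + C.T)
    C[np.diag_indices(n)] = 1.0
    return C


_MIN_CHOL_PIVOT = 1e-4  # conditional sd below this marks a degenerate cell


def _check_pivots(L: np.ndarray) -> np.ndarray:
    """Reject factorizations of a numerically degenerate correlation matrix.

    A Cholesky pivot is the conditional standard deviation of one cell
    given the preceding ones; at unit marginal variance a pivot near zero
    means two cells are effectively duplicates.  The profiled likelihood
    otherwise diverges in such corners (log|C| -> -inf), turning near
    singularity into a spurious optimum — the degeneracy that motivates
    subsampling in the first place.
    """
    if float(np.min(np.diag(L))) < _MIN_CHOL_PIVOT:
        raise SingularCorrelationError(
            "correlation matrix numerically singular: some cells are "
            "near-duplicates under these parameters; subsample more heavily "
            "(larger step)"
        )
    return L


def _chol(C: np.ndarray, ridge: float = 1e-10):
    """Cholesky with ridge and PD-repair fallbacks before failing."""
    try:
        return _check_pivots(linalg.cholesky(C, lower=True))
    except np.linalg.LinAlgError as err:
        if isinstance(err, SingularCorrelationError):
            raise
    try:
        return _check_pivots(
            linalg.cholesky(C + ridge * np.eye(len(C)), lower=True)
        )
    except np.linalg.LinAlgError as err:
        if isinstance(err, SingularCorrelationError):
            raise
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        repaired, _ = ensure_unit_diag_pd(C)
    try:
        return _check_pivots(
            linalg.cholesky(repaired + ridge * np.eye(len(C)), lower=True)
        )
    except SingularCorrelationError:
        raise
    except np.linalg.LinAlgError as exc:
        raise SingularCorrelationError(
            "correlation matrix numerically singular even after repair; "
            "adjacent cells are too self-similar - subsample more heavily "
            "(larger step)"
        ) from exc


def _profile(L: np.ndarray, y: np.ndarray, X: np.ndarray):
    """Profiled GLS quantities given the Cholesky factor of C.

    Returns (b, sigma2_ml, rss_gls, logdetC, XtCiX_inv, resid).
    """
    n = len(y)
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    XtX = Xw.T @ Xw
    Xty = Xw.T @ yw
    try:
        cf = linalg.cho_factor(XtX)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("design matrix is rank deficient") from exc
    b = linalg.cho_solve(cf, Xty)
    rw = yw - Xw @ b
    rss = float(rw @ rw)
    sigma2 = rss / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    XtX_inv = linalg.cho_solve(cf, np.eye(X.shape[1]))
    resid = y - X @ b
    return b, sigma2, rss, logdet, XtX_inv, resid


def _lambda_min_from_chol(L: np.ndarray, iters: int = 10) -> float:
    """Smallest eigenvalue of C from its Cholesky factor.

    Inverse power iteration: 1 / lambda_max(C^-1) via repeated triangular
    solves; O(n^2) per step.
    """
    n = L.shape[0]
    z = np.full(n, 1.0 / math.sqrt(n))
    nrm = 1.0
    for _ in range(iters):
        w = linalg.solve_triangular(L, z, lower=True)
        w = linalg.solve_triangular(L, w, lower=True, trans="T")
        nrm = float(np.linalg.norm(w))
        if nrm == 0.0:
            return np.inf
        z = w / nrm
    return 1.0 / nrm


def _guard_spectrum(L: np.ndarray, alpha: float) -> np.ndarray:
    """Reject correlation matrices whose spectrum betrays indefinite inputs.

    With positive semidefinite P and D the construction guarantees
    lambda_min(C) >= 1 - alpha.  The Gaussian kernel of great-circle
    (non-Euclidean) distances can be indefinite, which lets lambda_min(C)
    collapse toward zero at legal parameter values; the profiled likelihood
    then earns a spurious (1/2) log|C| bonus from that degenerate
    direction.  Anything far below the PSD bound is therefore a numerical
    artifact, not signal, and the parameter point is rejected.
    """
    floor = max(0.5 * (1.0 - alpha), 1e-6)
    if _lambda_min_from_chol(L) < floor:
        raise SingularCorrelationError(
            "correlation matrix numerically degenerate at these parameters "
            "(indefinite similarity input); subsample more heavily "
            "(larger step)"
        )
    return L


def negloglik(
    params: CorrelationParams,
    y: np.ndarray,
    X: np.ndarray,
    P: np.ndarray,
    d: np.ndarray,
) -> float:
    """Profiled negative log-likelihood at the given correlation parameters.

    ``b`` and ``sigma^2`` are profiled out:
    ``nll = (n/2) log(2 pi sigma2_hat) + (1/2) log|C| + n/2``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(y)
    if n < X.shape[1] + 1:
        raise ValueError("need n >= rank(X) + 1")
    C = build_correlation(params, P, d)
    L = _guard_spectrum(_chol(C), params.alpha)
    _, sigma2, _, logdet, _, _ = _profile(L, y, X)
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    return 0.5 * n * math.log(2.0 * math.pi * sigma2) + 0.5 * logdet + 0.5 * n


def _finalize_fit(
    method: str,
    params: CorrelationParams | None,
    y: np.ndarray,
    X: np.ndarray,
    names: list[str] | None,
    C: np.ndarray | None,
    optimizer: dict | None = None,
) -> FitResult:
    n, p = X.shape
    if C is None:
        C = np.eye(n)
    L = _chol(C)
    if params is not None:
        L = _guard_spectrum(L, params.alpha)
    b, sigma2, rss, logdet, XtX_inv, resid = _profile(L, y, X)
    ll = -(0.5 * n * math.log(2.0 * math.pi * max(sigma2, np.finfo(float).tiny))
           + 0.5 * logdet + 0.5 * n)
    se = np.sqrt(np.clip(sigma2 * np.diag(XtX_inv), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b / se, np.inf * np.sign(b))
    df = max(n - p, 1)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    fit = FitResult(
        method=method,
        names=list(names) if names is not None else [f"x{i}" for i in range(p)],
        coef=b,
        se=se,
        t=t,
        p=pvals,
        sigma2=sigma2,
        params=params,
        loglik=ll,
        n=n,
        optimizer=optimizer,
    )
    fit.predicted_r2 = _predicted_r2_from_chol(L, y, X, b, resid)
    return fit


def fit_ols(y, X, names: list[str] | None = None) -> FitResult:
    """Ordinary least squares: the GLS model with alpha pinned at 0."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    return _finalize_fit("ols", None, y, X, names, None)


def _starts(config: GLSConfig, d: np.ndarray) -> tuple[list[np.ndarray], float, float]:
    off = d[np.triu_indices(len(d), k=1)]
    med = float(np.median(off)) if off.size else 1.0
    dmax = float(off.max()) if off.size else 1.0
    lo = math.log(config.gamma_min)
    hi = math.log(max(config.gamma_max_factor * dmax, config.gamma_min * 2.0))
    pts = []
    for a, b, gf in itertools.product(
        config.alpha_starts, config.beta_starts, config.gamma_factors
    ):
        g = min(max(gf * med, config.gamma_min), math.exp(hi))
        pts.append(np.array([a, b, math.log(g)]))
    # the OLS corner: without it, a handful of high-alpha starts can trap the
    # search in a spuriously correlated local optimum on near-iid data
    g0 = min(max(med, config.gamma_min), math.exp(hi))
    pts.append(np.array([0.0, 0.5, math.log(g0)]))
    return pts, lo, hi


def fit_gls(
    y,
    X,
    P,
    d,
    config: GLSConfig | None = None,
    names: list[str] | None = None,
    extra_starts: list[CorrelationParams] | None = None,
) -> FitResult:
    """ML fit of the GLS model over (alpha, beta, gamma).

    Derivative-free bounded simplex search from multiple starts; the
    correlation parameters maximise the profiled likelihood, then
    coefficients, standard errors, t and two-sided p values (df = n minus
    the number of fixed-effect columns), the log-likelihood and the
    leave-one-out predicted R^2 are evaluated at the optimum.

    ``extra_starts`` lets a caller add warm starts (e.g. the optimum of a
    nesting model when refitting a reduced model for a likelihood-ratio
    test).
    """
    config = config or GLSConfig()
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    P = np.asarray(P, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")

    grid, lo, hi = _starts(config, d)
    if extra_starts:
        for ps in extra_starts:
            g = min(max(ps.gamma_km, config.gamma_min), math.exp(hi))
            grid.append(np.array([ps.alpha, ps.beta, math.log(g)]))

    def objective(theta: np.ndarray) -> float:
        a = float(np.clip(theta[0], 0.0, 1.0))
        b = float(np.clip(theta[1], 0.0, 1.0))
        g = float(np.clip(math.exp(theta[2]), config.gamma_min, math.exp(hi)))
        try:
            return negloglik(CorrelationParams(a, b, g), y, X, P, d)
        except SingularCorrelationError:
            return np.inf

    scored = sorted(grid, key=objective)
    rng = np.random.default_rng(config.seed)
    starts = []
    for k, theta in enumerate(scored[: config.n_starts]):
        if k > 0 and config.jitter > 0:
            theta = theta + rng.normal(0.0, config.jitter, size=3)
            theta[0] = np.clip(theta[0], 0.0, 1.0)
            theta[1] = np.clip(theta[1], 0.0, 1.0)
            theta[2] = np.clip(theta[2], lo, hi)
        starts.append(theta)

    bounds = [(0.0, 1.0), (0.0, 1.0), (lo, hi)]
    best = None
    trace = []
    for theta0 in starts:
        res = optimize.minimize(
            objective,
            theta0,
            method="Nelder-Mead",
            bounds=bounds,
            options={
                "fatol": config.ftol,
                "xatol": config.xtol,
                "maxiter": config.maxiter,
            },
        )
        trace.append(
            {"start": theta0.tolist(), "fun": float(res.fun), "success": bool(res.success)}
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"GLS optimizer failed to converge; trace: {trace}")

    a = float(np.clip(best.x[0], 0.0, 1.0))
    bpar = float(np.clip(best.x[1], 0.0, 1.0))
    g = float(np.clip(math.exp(best.x[2]), config.gamma_min, math.exp(hi)))
    params = CorrelationParams(a, bpar, g)
    C = build_correlation(params, P, d)
    return _finalize_fit(
        "gls",
        params,
        y,
        X,
        names,
        C,
        optimizer={"nll": float(best.fun), "n_starts": len(starts), "trace": trace},
    )


def fit_gls_fixed(
    params: CorrelationParams | None,
    y,
    X,
    P=None,
    d=None,
    names: list[str] | None = None,
) -> FitResult:
    """GLS fit at fixed, known correlation parameters (no optimization).

    With ``alpha = 0`` (or ``params=None``) this is exactly OLS.  Useful
    for pinning parameters in collapse checks and for evaluating a model at
    externally estimated correlation structure.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    C = None
    if params is not None:
        C = build_correlation(params, np.asarray(P), np.asarray(d))
    return _finalize_fit("gls-fixed", params, y, X, names, C)


def lr_test(full: FitResult, reduced: FitResult, df: int | None = None) -> LRResult:
    """Likelihood-ratio test: is the reduced model a significant worsening?

    ``df`` defaults to the number of dropped fixed-effect columns (k - 1
    for a k-level dummy-coded categorical).  Small negative statistics from
    optimizer tolerance are clamped to 0; larger ones indicate the reduced
    fit did not converge and should be refit warm-started from the full
    model's optimum.
    """
    if df is None:
        df = full.n_fixed - reduced.n_fixed
    if df < 1:
        raise ValueError("reduced model must drop at least one column")
    lr = 2.0 * (full.loglik - reduced.loglik)
    if lr < 0:
        if lr > -1e-4:
            lr = 0.0
        else:
            raise ValueError(
                f"negative LR statistic ({lr:.4g}): reduced model out-fits the "
                "full model; refit the reduced model warm-started from the "
                "full optimum"
            )
    return LRResult(lr=lr, df=df, p=float(stats.chi2.sf(lr, df)))


# -- prediction and residual diagnostics ------------------------------------


def _predicted_r2_from_chol(L, y, X, b, resid) -> float:
    """Leave-one-out conditional predicted R^2 from a factor of C.

    Uses the precision-matrix identity: with Q = C^{-1},
    r_i - C[i,-i] C[-i,-i]^{-1} r_{-i} = (Q r)_i / Q_ii, so the LOO
    conditional prediction is yhat_i = y_i - (Q r)_i / Q_ii.
    """
    n = len(y)
    if n < 3:
        raise ValueError("predicted R^2 needs n >= 3")
    Linv_r = linalg.solve_triangular(L, resid, lower=True)
    Qr = linalg.solve_triangular(L, Linv_r, lower=True, trans="T")
    Linv = linalg.solve_triangular(L, np.eye(n), lower=True)
    Qdiag = np.einsum("ij,ij->j", Linv, Linv)
    loo_err = Qr / Qdiag
    denom = float(np.sum((y - y.mean()) ** 2))
    if denom == 0.0:
        return 1.0 if np.allclose(loo_err, 0.0) else -np.inf
    return 1.0 - float(np.sum(loo_err**2)) / denom


def predicted_r2(fit: FitResult, y, X, P=None, d=None) -> float:
    """Leave-one-out predicted R^2 of a fitted model (see module docstring)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if fit.params is None:
        C = np.eye(len(y))
    else:
        C = build_correlation(fit.params, np.asarray(P), np.asarray(d))
    L = _chol(C)
    resid = y - X @ fit.coef
    return _predicted_r2_from_chol(L, y, X, fit.coef, resid)


def standardized_residuals(
    fit: FitResult, y, X, P=None, d=None
) -> ResidualReport:
    """Standardized and whitened residuals with hotspot flags.

    Standardized residuals are the raw residuals over sigma-hat (C has unit
    diagonal, so this is per-cell unit variance); cells beyond |1.96| are
    flagged as diversity hotspots/coldspots.  The Shapiro-Wilk normality
    check runs on the whitened residuals ``L^{-1} r / sigma``, which are iid
    standard normal when the model is correctly specified.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    resid = y - X @ fit.coef
    # a numerically perfect fit leaves only rounding noise, which would be
    # standardized by an equally tiny sigma-hat; report it as zero instead
    scale = max(1.0, float(np.max(np.abs(X @ fit.coef))))
    if np.max(np.abs(resid)) < 1e-10 * scale:
        z = np.zeros_like(resid)
        return ResidualReport(
            standardized=z,
            whitened=z,
            flags=np.zeros(len(resid), dtype=bool),
            shapiro_p=1.0,
        )
    sigma = math.sqrt(max(fit.sigma2, np.finfo(float).tiny))
    if fit.params is None:
        C = np.eye(len(y))
    else:
        C = build_correlation(fit.params, np.asarray(P), np.asarray(d))
    L = _chol(C)
    std = resid / sigma
    whitened = linalg.solve_triangular(L, resid, lower=True) / sigma
    if len(y) >= 3 and np.ptp(whitened) > 0:
        shapiro_p = float(stats.shapiro(whitened).pvalue)
    else:
        shapiro_p = 1.0
    return ResidualReport(
        standardized=std,
        whitened=whitened,
        flags=np.abs(std) >= 1.96,
        shapiro_p=shapiro_p,
    )
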