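"""Regression engines: log-space OLS and Pagel's-lambda PGLS.

Models are fit on log10-transformed traits, so every slope is the exponent of
a power law (y = 10^intercept * x^slope). Two estimators are provided:

* ordinary least squares, used for the joint shortest-autosome model
  log10(L_min) = delta + alpha*log10(C) + beta*log10(K) + gamma*log10(n);
* phylogenetic generalized least squares under Pagel's lambda, in which the
  residual covariance is sigma^2 * V(lambda), V(lambda) being the phylogenetic
  covariance matrix with off-diagonals scaled by lambda in [0, 1]. lambda is
  estimated by profiling the (restricted) likelihood: at each candidate lambda
  the coefficients and sigma^2 have closed-form GLS solutions, leaving a 1-D
  bounded maximization solved to 1e-6 absolute tolerance in lambda.

All GLS algebra goes through a Cholesky factorization of V (whitening); no
explicit matrix inverse is formed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .errors import (CollinearityError, DegenerateCovarianceError,
                     InsufficientDataError, InsufficientVariationError,
                     OptimizationError)
from .phylo import PhyloCovariance, Phylogeny, lambda_transform, normalize_name, prune_to, vcv
from .traits import Cohort, SpeciesRecord, build_trait_frame

logger = logging.getLogger("karyomorph.inference")

LAMBDA_TOL = 1e-6


@dataclass
class ModelSpec:
    """Names a response, its predictors, and how to estimate the model.

    The indicator ``s`` (0 = spatulate mammal, 1 = vermiform sauropsid) is the
    only legal non-logged predictor. ``lambda_mode`` is ``profile_ML``,
    ``profile_REML``, or ``fixed`` with ``lambda_fixed`` set.
    """

    response: str
    predictors: list[str]
    estimator: str = "PGLS"
    lambda_mode: str = "profile_REML"
    lambda_fixed: float | None = None

    def __post_init__(self) -> None:
        if not self.predictors or len(set(self.predictors)) != len(self.predictors):
            raise ValueError("predictors must be non-empty and distinct")
        if self.lambda_mode == "fixed" and self.lambda_fixed is None:
            raise ValueError("lambda_mode='fixed' requires lambda_fixed")


@dataclass
class RegressionResult:
    """Coefficients and inference for one fitted model."""

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    t_statistics: dict[str, float]
    p_values: dict[str, float]
    sigma2_hat: float
    r_squared: float
    n_obs: int
    log_likelihood: float
    lambda_hat: float | None = None
    estimator: str = "OLS"
    response: str | None = None
    lambda_at_boundary: bool = False

    @property
    def power_law_constant(self) -> float:
        """10**intercept: the multiplicative constant of the power-law form."""
        return 10.0 ** self.coefficients["intercept"]

    def predict_power_law(self, **natural_scale_predictors: float) -> float:
        """Evaluate y = 10^intercept * prod(x_j ^ slope_j) on the natural scale."""
        log10y = self.coefficients["intercept"]
        for name, value in natural_scale_predictors.items():
            if name == "s":
                log10y += self.coefficients[name] * value
            else:
                log10y += self.coefficients[name] * math.log10(value)
        return 10.0 ** log10y


def _as_matrix(y, X) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.shape[0]:
        raise ValueError("y and X row counts differ")
    return y, X


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if bad:
        raise CollinearityError(f"design matrix rank deficient; dependent columns: {bad}")


def _solve_ls(yw: np.ndarray, Xw: np.ndarray):
    """Least squares on whitened data via QR; returns beta, RSS, (X'X)^-1."""
    Q, R = np.linalg.qr(Xw)
    beta = linalg.solve_triangular(R, Q.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    Rinv = linalg.solve_triangular(R, np.eye(R.shape[0]))
    xtx_inv = Rinv @ Rinv.T
    return beta, rss, xtx_inv


def _finalize(beta, rss, xtx_inv, n, k, names, r_squared, log_likelihood,
              lambda_hat=None, estimator="OLS", response=None,
              boundary=False) -> RegressionResult:
    df = n - k
    sigma2 = rss / df
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return RegressionResult(
        coefficients=dict(zip(names, beta.tolist())),
        standard_errors=dict(zip(names, se.tolist())),
        t_statistics=dict(zip(names, t.tolist())),
        p_values=dict(zip(names, p.tolist())),
        sigma2_hat=sigma2, r_squared=r_squared, n_obs=n,
        log_likelihood=log_likelihood, lambda_hat=lambda_hat,
        estimator=estimator, response=response, lambda_at_boundary=boundary)


def ols_fit(y, X, names: Sequence[str] | None = None,
            response: str | None = None) -> RegressionResult:
    """Ordinary least squares with an explicit design matrix (intercept included).

    Standard errors use the unbiased residual-variance estimate; t-tests are
    two-sided with N - k degrees of freedom; R^2 is about the mean.
    """
    y, X = _as_matrix(y, X)
    n, k = X.shape
    if names is None:
        names = ["intercept"] + [f"x{i}" for i in range(1, k)]
    if n <= k:
        raise InsufficientDataError(f"need more than {k} observations, got {n}")
    _check_rank(X, names)
    beta, rss, xtx_inv = _solve_ls(y, X)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else math.nan
    sigma2_ml = rss / n
    ll = -0.5 * (n * math.log(2 * math.pi * sigma2_ml) + n)
    return _finalize(beta, rss, xtx_inv, n, k, list(names), r2, ll,
                     estimator="OLS", response=response)


def fit_lmin_model(records: Iterable[SpeciesRecord]) -> RegressionResult:
    """Joint OLS of log10(L_min) on log10(C), log10(K), log10(n).

    Species missing any of C, K, n, or L_min are dropped listwise. The fitted
    intercept is delta (power-law constant D = 10^delta) and the slopes are
    the exponents alpha (genome size), beta (dispersity), gamma (chromosome
    number).
    """
    frame = build_trait_frame(records)
    cols = ["log10_Lmin", "log10_C", "log10_K", "log10_n"]
    sub = frame.dropna(subset=cols)
    if len(sub) <= 4:
        raise InsufficientDataError(
            f"joint L_min model needs N > 4 complete species, got {len(sub)}")
    X = np.column_stack([np.ones(len(sub)), sub["log10_C"], sub["log10_K"],
                         sub["log10_n"]])
    return ols_fit(sub["log10_Lmin"].to_numpy(), X,
                   names=["intercept", "log10_C", "log10_K", "log10_n"],
                   response="log10_Lmin")


def _whiten(V: np.ndarray):
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError as exc:
        raise DegenerateCovarianceError(
            "phylogenetic covariance is singular (duplicated tips or zero "
            "terminal branches?)") from exc
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return L, logdet


def _gls_core(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """GLS estimates plus both likelihood criteria at one fixed covariance."""
    n, k = X.shape
    L, logdetV = _whiten(V)
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    beta, rss, xtx_inv = _solve_ls(yw, Xw)
    sigma2_ml = rss / n
    ll_ml = -0.5 * (n * math.log(2 * math.pi * sigma2_ml) + logdetV + n)
    dfr = n - k
    sigma2_reml = rss / dfr
    sign, logdet_xtx = np.linalg.slogdet(Xw.T @ Xw)
    ll_reml = -0.5 * (dfr * math.log(2 * math.pi * sigma2_reml) + logdetV
                      + logdet_xtx + dfr)
    return beta, rss, xtx_inv, ll_ml, ll_reml, L


def gls_fit(y, X, V: PhyloCovariance | np.ndarray,
            names: Sequence[str] | None = None, response: str | None = None,
            ) -> RegressionResult:
    """Generalized least squares with a fixed residual covariance matrix.

    beta = (X' V^-1 X)^-1 X' V^-1 y computed by Cholesky whitening;
    sigma2_hat = e' V^-1 e / (N - k); the reported log-likelihood is the
    multivariate-normal (ML) likelihood at the estimates. With V = I this
    reproduces OLS exactly.
    """
    y, X = _as_matrix(y, X)
    lam = None
    if isinstance(V, PhyloCovariance):
        lam = V.lambda_applied
        V = V.matrix
    V = np.asarray(V, dtype=float)
    n, k = X.shape
    if names is None:
        names = ["intercept"] + [f"x{i}" for i in range(1, k)]
    if n <= k:
        raise InsufficientDataError(f"need more than {k} observations, got {n}")
    _check_rank(X, names)
    beta, rss, xtx_inv, ll_ml, _, L = _gls_core(y, X, V)
    r2 = _whitened_r2(y, X, beta, L)
    return _finalize(beta, rss, xtx_inv, n, k, list(names), r2, ll_ml,
                     lambda_hat=lam, estimator="GLS", response=response)


def _whitened_r2(y: np.ndarray, X: np.ndarray, beta: np.ndarray,
                 L: np.ndarray) -> float:
    """R^2 on the whitened model, relative to a GLS intercept-only baseline.

    1 - (e' V^-1 e) / (e0' V^-1 e0), where e are the model residuals and e0
    the residuals about the GLS-estimated grand mean. Reduces to ordinary R^2
    when V = I.
    """
    yw = linalg.solve_triangular(L, y, lower=True)
    ones_w = linalg.solve_triangular(L, np.ones_like(y), lower=True)
    mu = float(ones_w @ yw) / float(ones_w @ ones_w)
    e0w = yw - ones_w * mu
    ew = linalg.solve_triangular(L, y - X @ beta, lower=True)
    denom = float(e0w @ e0w)
    return 1.0 - float(ew @ ew) / denom if denom > 0 else math.nan


def profile_lambda(y, X, V: PhyloCovariance, mode: str = "profile_REML",
                   ) -> tuple[float, RegressionResult]:
    """Estimate Pagel's lambda by bounded profile (restricted) likelihood.

    At each lambda in [0, 1] the GLS coefficients and sigma^2 are profiled out
    analytically; the remaining scalar objective is maximized by Brent-style
    bounded search to 1e-6 absolute tolerance, with both endpoints checked
    explicitly. Boundary solutions are flagged on the returned result.
    """
    y, X = _as_matrix(y, X)
    if mode not in ("profile_ML", "profile_REML"):
        raise ValueError(f"unknown lambda mode: {mode}")
    use_reml = mode == "profile_REML"

    def objective(lam: float) -> float:
        try:
            Vlam = lambda_transform(V, lam).matrix
            _, _, _, ll_ml, ll_reml, _ = _gls_core(y, X, Vlam)
        except DegenerateCovarianceError:
            return math.inf
        ll = ll_reml if use_reml else ll_ml
        return -ll if math.isfinite(ll) else math.inf

    res = optimize.minimize_scalar(objective, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": LAMBDA_TOL})
    candidates = [(objective(0.0), 0.0), (objective(1.0), 1.0),
                  (float(res.fun), float(res.x))]
    best_obj, lam_hat = min(candidates, key=lambda c: c[0])
    if not math.isfinite(best_obj):
        raise OptimizationError("profile likelihood is non-finite over [0, 1]; "
                                "check the covariance matrix for singularity")
    boundary = lam_hat in (0.0, 1.0)
    if boundary:
        logger.info("lambda estimate at boundary: %g", lam_hat)
    fit = gls_fit(y, X, lambda_transform(V, lam_hat))
    fit.lambda_hat = lam_hat
    fit.lambda_at_boundary = boundary
    fit.estimator = "PGLS"
    return lam_hat, fit


def pgls_fit(spec: ModelSpec, table: pd.DataFrame, tree: Phylogeny,
             ) -> RegressionResult:
    """Fit one named model by PGLS (or OLS) on an aligned trait table.

    Performs listwise deletion over the model's columns, prunes the tree to
    the surviving species, orders rows to the covariance matrix's species
    order, then estimates lambda (profile ML/REML, or fixed) and the GLS
    coefficients, standard errors, two-sided t-tests (df = N - k), whitened
    R^2, and the power-law constant 10^intercept.
    """
    cols = [spec.response] + spec.predictors
    sub = table.dropna(subset=cols).copy()
    k = len(spec.predictors) + 1
    if len(sub) <= k + 1:
        raise InsufficientDataError(
            f"model {spec.response} ~ {spec.predictors}: only {len(sub)} complete rows")
    for pred in spec.predictors:
        if np.ptp(sub[pred].to_numpy()) == 0.0:
            raise InsufficientVariationError(
                f"predictor {pred} has no variation after listwise deletion")
    names = ["intercept"] + spec.predictors

    if spec.estimator == "OLS":
        X = np.column_stack([np.ones(len(sub))] + [sub[p] for p in spec.predictors])
        return ols_fit(sub[spec.response].to_numpy(), X, names=names,
                       response=spec.response)

    sub["_name"] = sub["species"].map(normalize_name)
    pruned, dropped = prune_to(tree, sub["_name"])
    if dropped:
        sub = sub[~sub["_name"].isin(dropped)]
    cov = vcv(pruned)
    sub = sub.set_index("_name").loc[cov.species]
    y = sub[spec.response].to_numpy()
    X = np.column_stack([np.ones(len(sub))] + [sub[p] for p in spec.predictors])

    if spec.lambda_mode == "fixed":
        fit = gls_fit(y, X, lambda_transform(cov, spec.lambda_fixed),
                      names=names, response=spec.response)
        fit.estimator = "PGLS"
        return fit
    lam_hat, fit = profile_lambda(y, X, cov, mode=spec.lambda_mode)
    fit.coefficients = dict(zip(names, fit.coefficients.values()))
    fit.standard_errors = dict(zip(names, fit.standard_errors.values()))
    fit.t_statistics = dict(zip(names, fit.t_statistics.values()))
    fit.p_values = dict(zip(names, fit.p_values.values()))
    fit.response = spec.response
    return fit


# ---------------------------------------------------------------------------
# The cohort regression battery

#: per-cohort predictors: head dimension, genome size, normalized dimension
_COHORT_PREDICTORS = {
    Cohort.SPATULATE_MAMMAL: ["log10_area", "log10_C", "log10_area_per_pg"],
    Cohort.VERMIFORM_SAUROPSID: ["log10_length", "log10_C", "log10_length_per_pg"],
}
_RESPONSES = ["log10_n", "log10_K"]
#: pooled (both-cohort) models: karyotype vs genome size and vs the shape indicator
_POOLED_PREDICTORS = ["log10_C", "s"]

BATTERY_COLUMNS = ["cohort", "response", "predictor", "estimator", "N", "lambda_hat",
                   "intercept", "slope", "SE_slope", "t", "p", "R2", "significant",
                   "power_law_constant"]


def _battery_row(cohort: str, response: str, predictor: str, lambda_mode: str,
                 table: pd.DataFrame, tree: Phylogeny, alpha: float) -> dict:
    row = {"cohort": cohort, "response": response, "predictor": predictor,
           "estimator": "PGLS", "N": 0, "lambda_hat": math.nan,
           "intercept": math.nan, "slope": math.nan, "SE_slope": math.nan,
           "t": math.nan, "p": math.nan, "R2": math.nan, "significant": "NA",
           "power_law_constant": math.nan}
    try:
        fit = pgls_fit(ModelSpec(response, [predictor], estimator="PGLS",
                                 lambda_mode=lambda_mode), table, tree)
    except (InsufficientDataError, InsufficientVariationError) as exc:
        logger.warning("battery cell %s/%s~%s not applicable: %s",
                       cohort, response, predictor, exc)
        return row
    row.update(N=fit.n_obs, lambda_hat=fit.lambda_hat,
               intercept=fit.coefficients["intercept"],
               slope=fit.coefficients[predictor],
               SE_slope=fit.standard_errors[predictor],
               t=fit.t_statistics[predictor], p=fit.p_values[predictor],
               R2=fit.r_squared,
               significant=int(fit.p_values[predictor] < alpha),
               power_law_constant=fit.power_law_constant)
    return row


def run_battery(records: Sequence[SpeciesRecord], tree: Phylogeny,
                correction_um: float = 1.0, lambda_mode: str = "profile_REML",
                alpha: float = 0.05) -> pd.DataFrame:
    """Fit the full cohort-wise regression battery.

    Per cohort, six PGLS models: each karyotype parameter (haploid number n,
    dispersity K) against the cohort's head dimension (projected area for
    spatulate mammals, length for vermiform sauropsids), genome size C, and
    the genome-normalized dimension. Four pooled models follow: n and K
    against C across both cohorts, and against the head-shape indicator s.
    Each slope is flagged significant at the two-sided level ``alpha``
    (default 0.05). Cells that cannot be fit (absent cohort, missing data)
    are emitted with N = 0 and significant = "NA". Row order is deterministic.
    """
    table = build_trait_frame(records, correction_um)
    rows: list[dict] = []
    for cohort in (Cohort.SPATULATE_MAMMAL, Cohort.VERMIFORM_SAUROPSID):
        sub = table[table["cohort"] == cohort.value]
        for response in _RESPONSES:
            for predictor in _COHORT_PREDICTORS[cohort]:
                rows.append(_battery_row(cohort.value, response, predictor,
                                         lambda_mode, sub, tree, alpha))
    for response in _RESPONSES:
        for predictor in _POOLED_PREDICTORS:
            rows.append(_battery_row("pooled", response, predictor,
                                     lambda_mode, table, tree, alpha))
    return pd.DataFrame(rows, columns=BATTERY_COLUMNS)
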