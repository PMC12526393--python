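"""Tree-level biomass allometry with variance-function weighting.

Young trees show strongly heteroscedastic biomass: the spread of component
dry mass grows with stem basal diameter. Log-transforming and back-
transforming introduces bias, so the models here stay on the original
scale and remove the heteroscedasticity by weighting instead:

1. *Pass 1* -- fit the power model ``BC = b0 * x^b1`` (or
   ``b0 * d0^b1 * h^b2``) by unweighted nonlinear least squares; order the
   residuals by the predictor, group them in sets of 25, and regress
   ``ln(group residual variance)`` on ``ln(group mean predictor)``. The
   slope is the variance exponent ``lambda`` in
   ``Var(r) = alpha * x^lambda``, giving per-tree weights
   ``w = x^-lambda``.
2. *Pass 2* -- refit with those weights, re-estimate ``(alpha, lambda)``
   from the new residuals, recompute the weights and fit once more. The
   final weighted model is checked with a Breusch-Pagan test on the
   weight-standardised residuals; a chi-square p-value above 0.05 means
   the weighting removed the heteroscedasticity.

If a fit fails to converge, response values above the 99th percentile are
treated as outliers, removed, and the procedure restarts.

The public surface is statsmodels-like: build a :class:`TreeBiomassModel`
from a sample-tree table, call :meth:`~TreeBiomassModel.fit`, and read
estimates, diagnostics and ``summary()`` off the returned
:class:`TreeBiomassResults`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.diagnostic import het_breuschpagan

__all__ = [
    "TreeBiomassModel",
    "TreeBiomassResults",
    "VarianceProfile",
    "variance_profile",
    "estimate_variance_exponent",
    "compute_weights",
    "breusch_pagan",
    "ConvergenceError",
    "FitError",
    "CollinearityWarning",
]

FORMS = ("d0", "h", "d0h")
COMPONENTS = ("foliage", "woody")

#: column holding each component's dry mass in a sample-tree table
COMPONENT_COLUMNS = {"foliage": "foliage_g", "woody": "woody_g"}

#: a group variance below this (relative to the squared response scale)
#: is treated as exactly zero -- the ln-ln variance fit is then impossible
_ZERO_VAR_RTOL = 1e-20


class ConvergenceError(RuntimeError):
    """Nonlinear least squares failed to converge.

    Carries the optimizer result (``trace``) so callers can inspect the
    iteration count and termination status before applying the outlier rule.
    """

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class FitError(RuntimeError):
    """The fitting procedure failed even after outlier removal."""


class CollinearityWarning(UserWarning):
    """Predictors are (nearly) collinear; the covariance is ill-conditioned."""


# ---------------------------------------------------------------------------
# variance profile and weights
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VarianceProfile:
    """Grouped residual variances along the predictor axis.

    ``groups`` lists ``(mean predictor, residual variance, group size)``
    ordered by mean predictor.
    """

    mean_predictor: np.ndarray
    variance: np.ndarray
    size: np.ndarray

    @property
    def groups(self) -> list[tuple[float, float, int]]:
        return list(
            zip(self.mean_predictor.tolist(), self.variance.tolist(), self.size.tolist())
        )

    def __len__(self) -> int:
        return len(self.mean_predictor)


def variance_profile(
    residuals: np.ndarray, predictor_values: np.ndarray, group_size: int = 25
) -> VarianceProfile:
    """Group residuals by predictor and compute per-group variances.

    Residual/predictor pairs are sorted by the predictor and cut into
    consecutive groups of ``group_size``. When the sample size is not a
    multiple of ``group_size``, a short final group with fewer than
    ``(group_size + 1) // 2`` members is merged into the preceding group
    (so 111 trees in sets of 25 give 4 groups, the last of size 36);
    otherwise it is kept as its own group.
    """
    residuals = np.asarray(residuals, dtype=float)
    predictor_values = np.asarray(predictor_values, dtype=float)
    if residuals.shape != predictor_values.shape:
        raise ValueError("residuals and predictor_values must align")
    n = residuals.size
    if n < 2 * group_size:
        raise ValueError(
            f"need at least {2 * group_size} points for a variance profile, got {n}"
        )
    order = np.argsort(predictor_values, kind="stable")
    r = residuals[order]
    x = predictor_values[order]
    edges = list(range(0, n, group_size))
    remainder = n - edges[-1]
    if remainder < (group_size + 1) // 2 and len(edges) > 1:
        edges.pop()  # merge short tail into the previous group
    edges.append(n)
    means, variances, sizes = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        means.append(float(x[lo:hi].mean()))
        variances.append(float(r[lo:hi].var(ddof=1)))
        sizes.append(hi - lo)
    return VarianceProfile(np.array(means), np.array(variances), np.array(sizes))


def estimate_variance_exponent(profile: VarianceProfile) -> tuple[float, float]:
    """Fit ``ln(variance) = ln(alpha) + lambda * ln(mean predictor)``.

    Returns ``(alpha, lambda)`` from an ordinary least-squares line through
    the ln-ln profile. Raises if any group variance is zero (the log is
    undefined; residuals are effectively deterministic).
    """
    if len(profile) < 2:
        raise ValueError("need at least 2 groups to estimate the variance exponent")
    scale = float(np.max(profile.mean_predictor)) ** 2
    if np.any(profile.variance <= _ZERO_VAR_RTOL * scale):
        raise ValueError("zero group variance: cannot fit the ln-ln variance function")
    ln_x = np.log(profile.mean_predictor)
    ln_v = np.log(profile.variance)
    slope, intercept = np.polyfit(ln_x, ln_v, 1)
    return float(np.exp(intercept)), float(slope)


def compute_weights(predictor_values: np.ndarray, lam: float) -> np.ndarray:
    """Variance-function weights ``w_j = predictor_j ** -lambda``."""
    x = np.asarray(predictor_values, dtype=float)
    if np.any(x <= 0):
        raise ValueError("weights require strictly positive predictor values")
    return x**-lam


# ---------------------------------------------------------------------------
# power-form evaluation and nonlinear least squares
# ---------------------------------------------------------------------------


def _n_coef(form: str) -> int:
    return 3 if form == "d0h" else 2


def _eval_form(form: str, params: np.ndarray, d0, h) -> np.ndarray:
    if form == "d0":
        return params[0] * np.asarray(d0, dtype=float) ** params[1]
    if form == "h":
        return params[0] * np.asarray(h, dtype=float) ** params[1]
    if form == "d0h":
        return (
            params[0]
            * np.asarray(d0, dtype=float) ** params[1]
            * np.asarray(h, dtype=float) ** params[2]
        )
    raise ValueError(f"unknown form {form!r}; expected one of {FORMS}")


def _loglog_start(form: str, y: np.ndarray, d0: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Start values from an OLS fit of ln(y) on the log predictors."""
    cols = [np.ones_like(y)]
    if form in ("d0", "d0h"):
        cols.append(np.log(d0))
    if form in ("h", "d0h"):
        cols.append(np.log(h))
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, np.log(y), rcond=None)
    return np.concatenate([[np.exp(beta[0])], beta[1:]])


def _nls(
    form: str,
    y: np.ndarray,
    d0: np.ndarray,
    h: np.ndarray,
    weights: np.ndarray,
    x0: np.ndarray,
    xtol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted nonlinear least squares; returns (params, covariance)."""
    sw = np.sqrt(weights)

    def fun(theta):
        return sw * (y - _eval_form(form, theta, d0, h))

    res = optimize.least_squares(
        fun, x0, method="lm", xtol=xtol, ftol=xtol, gtol=1e-12, max_nfev=max_iter * len(x0)
    )
    if not res.success:
        raise ConvergenceError(
            f"nonlinear least squares did not converge (status {res.status}, "
            f"{res.nfev} evaluations)",
            trace=res,
        )
    n, p = y.size, x0.size
    jtj = res.jac.T @ res.jac
    cond = np.linalg.cond(jtj)
    if cond > 1e12:
        warnings.warn(
            f"near-singular parameter covariance (condition number {cond:.2e}); "
            "predictors may be collinear",
            CollinearityWarning,
            stacklevel=2,
        )
    s2 = 2.0 * res.cost / max(n - p, 1)
    cov = np.linalg.pinv(jtj) * s2
    return res.x, cov


# ---------------------------------------------------------------------------
# Breusch-Pagan test
# ---------------------------------------------------------------------------


def breusch_pagan(
    residuals: np.ndarray,
    predictors: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[float, float]:
    """Breusch-Pagan LM test of the (weight-standardised) residuals.

    The squared standardised residuals ``(r_i * sqrt(w_i))^2`` are
    regressed on the mean-model predictors; the statistic is ``n * R^2``
    against a chi-square with one degree of freedom per predictor. Applied
    after weighting, a p-value above 0.05 indicates the variance-function
    weights removed the heteroscedasticity.

    Parameters
    ----------
    residuals
        Raw residuals ``y - yhat``.
    predictors
        1-D predictor vector or 2-D ``(n, k)`` predictor matrix
        (no constant column).
    weights
        Optional per-point weights; omitted means unweighted (all 1).
    """
    r = np.asarray(residuals, dtype=float)
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if weights is not None:
        r = r * np.sqrt(np.asarray(weights, dtype=float))
    r2 = r**2
    if np.allclose(r2, r2.mean(), atol=1e-30 + 1e-12 * max(r2.mean(), 1e-300)):
        # constant squared residuals: auxiliary R^2 is exactly 0
        return 0.0, 1.0
    exog = np.column_stack([np.ones(len(r)), X])
    lm, lm_pvalue, _, _ = het_breuschpagan(r, exog)
    return float(lm), float(lm_pvalue)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class TreeBiomassModel:
    """Power-law biomass model for one component of one sample-tree table.

    Parameters
    ----------
    data
        Sample-tree table with columns ``d0_mm``, ``h_m`` and the component
        mass column (``foliage_g`` or ``woody_g``).
    component
        ``"foliage"`` or ``"woody"``.
    form
        ``"d0"`` (mass ~ b0 * d0^b1), ``"h"`` (mass ~ b0 * h^b1) or
        ``"d0h"`` (mass ~ b0 * d0^b1 * h^b2).
    group_size
        Residuals per group in the variance profile (default 25).
    max_iter
        Iteration cap for each nonlinear fit.
    xtol
        Relative coefficient-change convergence tolerance.

    Examples
    --------
    >>> model = TreeBiomassModel(trees, component="foliage", form="d0")
    >>> res = model.fit()
    >>> res.predict(d0=60.0)  # doctest: +SKIP
    """

    def __init__(
        self,
        data: pd.DataFrame,
        component: str = "foliage",
        form: str = "d0",
        group_size: int = 25,
        max_iter: int = 200,
        xtol: float = 1e-8,
    ):
        if component not in COMPONENTS:
            raise ValueError(f"component must be one of {COMPONENTS}, got {component!r}")
        if form not in FORMS:
            raise ValueError(f"form must be one of {FORMS}, got {form!r}")
        required = {"d0_mm", "h_m", COMPONENT_COLUMNS[component]}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"data is missing columns {sorted(missing)}")
        n_min = _n_coef(form) + 2
        if len(data) < n_min:
            raise ValueError(f"need at least {n_min} trees for form {form!r}")
        if (data["d0_mm"] <= 0).any() or (data["h_m"] <= 0).any():
            raise ValueError("predictors must be strictly positive")
        self.data = data.reset_index(drop=True)
        self.component = component
        self.form = form
        self.group_size = group_size
        self.max_iter = max_iter
        self.xtol = xtol

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "TreeBiomassModel":
        df = pd.read_csv(path)
        if df.empty:
            raise ValueError(f"empty sample-tree table: {path}")
        return cls(df, **kwargs)

    # -- data accessors ----------------------------------------------------

    @property
    def response(self) -> np.ndarray:
        return self.data[COMPONENT_COLUMNS[self.component]].to_numpy(dtype=float)

    @property
    def weighting_predictor(self) -> np.ndarray:
        """Predictor used in the variance function: d0 for forms d0 and
        d0h (the variance law is written in d0), h for form h."""
        col = "h_m" if self.form == "h" else "d0_mm"
        return self.data[col].to_numpy(dtype=float)

    def _predictor_matrix(self) -> np.ndarray:
        cols = []
        if self.form in ("d0", "d0h"):
            cols.append(self.data["d0_mm"].to_numpy(dtype=float))
        if self.form in ("h", "d0h"):
            cols.append(self.data["h_m"].to_numpy(dtype=float))
        return np.column_stack(cols)

    # -- single fits -------------------------------------------------------

    def _fit_once(
        self, data: pd.DataFrame, weights: np.ndarray, lam: float, alpha: float
    ) -> "TreeBiomassResults":
        y = data[COMPONENT_COLUMNS[self.component]].to_numpy(dtype=float)
        d0 = data["d0_mm"].to_numpy(dtype=float)
        h = data["h_m"].to_numpy(dtype=float)
        x0 = _loglog_start(self.form, y, d0, h)
        params, cov = _nls(self.form, y, d0, h, weights, x0, self.xtol, self.max_iter)
        fitted = _eval_form(self.form, params, d0, h)
        return TreeBiomassResults(
            model=self,
            data=data,
            params=params,
            cov_params=cov,
            weights=weights,
            lambda_=lam,
            alpha=alpha,
            fittedvalues=fitted,
            resid=y - fitted,
            n_outliers_removed=0,
        )

    def fit_unweighted(self, data: pd.DataFrame | None = None) -> "TreeBiomassResults":
        """Pass-1 fit: unit weights, start values from ln-ln OLS."""
        data = self.data if data is None else data
        return self._fit_once(data, np.ones(len(data)), 0.0, float("nan"))

    def fit_weighted(
        self, weights: np.ndarray, data: pd.DataFrame | None = None, lam: float = float("nan")
    ) -> "TreeBiomassResults":
        """Weighted fit minimising ``sum w_i (BC_i - f_i)^2``."""
        data = self.data if data is None else data
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (len(data),):
            raise ValueError("weights must align with the tree table")
        if np.any(weights <= 0):
            raise ValueError("weights must be strictly positive")
        return self._fit_once(data, weights, lam, float("nan"))

    # -- two-pass procedure ------------------------------------------------

    def fit(self, max_outlier_rounds: int = 3) -> "TreeBiomassResults":
        """Run the full two-pass weighted procedure.

        Pass 1 estimates the variance exponent from the unweighted fit's
        residual profile; pass 2 refits with the implied weights,
        re-estimates ``(alpha, lambda)`` and produces the final weighted
        model. Residuals with zero profile variance (noise-free data)
        degrade gracefully to the unweighted fit with a warning. A fit
        that fails to converge triggers removal of response values above
        the 99th percentile and a restart.
        """
        if len(self.data) < 2 * self.group_size:
            raise ValueError(
                f"the weighting procedure needs at least {2 * self.group_size} trees"
            )
        data = self.data
        removed_total = 0
        last_err: Exception | None = None
        for _ in range(max_outlier_rounds + 1):
            try:
                result = self._run_two_pass(data)
                result.n_outliers_removed = removed_total
                return result
            except ConvergenceError as err:
                last_err = err
                y = data[COMPONENT_COLUMNS[self.component]].to_numpy(dtype=float)
                cut = np.percentile(y, 99)
                keep = y <= cut
                n_removed = int((~keep).sum())
                if n_removed == 0:
                    break
                removed_total += n_removed
                data = data.loc[keep].reset_index(drop=True)
        raise FitError(
            f"fitting failed after removing {removed_total} outliers: {last_err}"
        )

    def _run_two_pass(self, data: pd.DataFrame) -> "TreeBiomassResults":
        col = "h_m" if self.form == "h" else "d0_mm"
        x_w = data[col].to_numpy(dtype=float)

        pass1 = self.fit_unweighted(data)
        try:
            profile1 = variance_profile(pass1.resid, x_w, self.group_size)
            _, lam1 = estimate_variance_exponent(profile1)
        except ValueError as err:
            warnings.warn(
                f"variance-exponent estimation rejected ({err}); "
                "falling back to the unweighted fit",
                UserWarning,
                stacklevel=2,
            )
            return self._finalise(pass1, data)

        w1 = compute_weights(x_w, lam1)
        pass2 = self._fit_once(data, w1, lam1, float("nan"))
        profile2 = variance_profile(pass2.resid, x_w, self.group_size)
        alpha2, lam2 = estimate_variance_exponent(profile2)
        w2 = compute_weights(x_w, lam2)
        final = self._fit_once(data, w2, lam2, alpha2)
        return self._finalise(final, data)

    def _finalise(self, result: "TreeBiomassResults", data: pd.DataFrame) -> "TreeBiomassResults":
        cols = []
        if self.form in ("d0", "d0h"):
            cols.append(data["d0_mm"].to_numpy(dtype=float))
        if self.form in ("h", "d0h"):
            cols.append(data["h_m"].to_numpy(dtype=float))
        X = np.column_stack(cols)
        result.bp_chi2, result.bp_pvalue = breusch_pagan(result.resid, X, result.weights)
        return result


@dataclass
class TreeBiomassResults:
    """Fitted tree-level biomass model.

    Attributes follow statsmodels conventions: ``params``, ``bse``,
    ``pvalues``, ``cov_params``, ``aic``; the weighting state is carried in
    ``lambda_`` (variance exponent), ``alpha`` (variance scale) and
    ``weights``. ``mse`` and ``rse`` are on the weighted scale, so
    ``mse = rse^2 * (n - p) / n`` holds on every fit.
    """

    model: TreeBiomassModel
    data: pd.DataFrame
    params: np.ndarray
    cov_params: np.ndarray
    weights: np.ndarray
    lambda_: float
    alpha: float
    fittedvalues: np.ndarray
    resid: np.ndarray
    n_outliers_removed: int = 0
    bp_chi2: float = field(default=float("nan"))
    bp_pvalue: float = field(default=float("nan"))

    # -- derived quantities ------------------------------------------------

    @property
    def component(self) -> str:
        return self.model.component

    @property
    def form(self) -> str:
        return self.model.form

    @property
    def n_used(self) -> int:
        return len(self.data)

    @property
    def df_resid(self) -> int:
        return self.n_used - len(self.params)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def tvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.t.sf(np.abs(self.tvalues), self.df_resid)

    @property
    def _wrss(self) -> float:
        return float(np.sum(self.weights * self.resid**2))

    @property
    def mse(self) -> float:
        """Weighted mean squared error, ``sum(w r^2) / n``."""
        return self._wrss / self.n_used

    @property
    def rse(self) -> float:
        """Weighted residual standard error, ``sqrt(sum(w r^2) / (n - p))``."""
        return float(np.sqrt(self._wrss / self.df_resid))

    @property
    def aic(self) -> float:
        """AIC of the weighted Gaussian likelihood with sigma^2 profiled out.

        Comparable across forms fitted to the same trees with the same
        weights; the absolute level depends on the weighting.
        """
        n = self.n_used
        sigma2 = self._wrss / n
        if sigma2 <= 0:
            return -np.inf
        loglik = (
            -0.5 * n * np.log(2 * np.pi * sigma2)
            + 0.5 * float(np.sum(np.log(self.weights)))
            - 0.5 * n
        )
        return float(-2 * loglik + 2 * (len(self.params) + 1))

    # -- prediction --------------------------------------------------------

    def predict(self, d0=None, h=None) -> np.ndarray | float:
        """Evaluate the fitted power form (grams).

        ``d0`` in mm and/or ``h`` in m as the form requires; scalar in,
        scalar out.
        """
        scalar = (d0 is None or np.ndim(d0) == 0) and (h is None or np.ndim(h) == 0)
        d0a, ha = self._check_predictors(d0, h)
        out = _eval_form(self.form, self.params, d0a, ha)
        return float(out[0]) if scalar else out

    def _check_predictors(self, d0, h):
        need_d0 = self.form in ("d0", "d0h")
        need_h = self.form in ("h", "d0h")
        if need_d0 and d0 is None:
            raise ValueError(f"form {self.form!r} requires d0")
        if need_h and h is None:
            raise ValueError(f"form {self.form!r} requires h")
        d0a = np.atleast_1d(np.asarray(d0, dtype=float)) if d0 is not None else None
        ha = np.atleast_1d(np.asarray(h, dtype=float)) if h is not None else None
        for name, arr, needed in (("d0", d0a, need_d0), ("h", ha, need_h)):
            if needed and np.any(arr <= 0):
                raise ValueError(f"{name} must be strictly positive")
        return d0a, ha

    def predict_interval(
        self,
        d0=None,
        h=None,
        n_draws: int = 2000,
        seed: int | None = None,
        level: float = 0.95,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Monte-Carlo confidence band for the fitted curve.

        Coefficient vectors are drawn from the multivariate normal with the
        fitted mean and covariance; the band is the central ``level``
        percentile range of the implied predictions. This captures the
        nonlinearity of the power form that a first-order (delta-method)
        linearisation misses.
        """
        if not np.all(np.isfinite(self.cov_params)):
            raise ValueError("covariance matrix is not finite; cannot simulate")
        scalar = (d0 is None or np.ndim(d0) == 0) and (h is None or np.ndim(h) == 0)
        d0a, ha = self._check_predictors(d0, h)
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(
            self.params, self.cov_params, size=n_draws, method="svd"
        )
        n_points = len(d0a) if d0a is not None else len(ha)
        sims = np.empty((n_draws, n_points))
        for i, theta in enumerate(draws):
            sims[i] = _eval_form(self.form, theta, d0a, ha)
        tail = 100 * (1 - level) / 2
        lower = np.percentile(sims, tail, axis=0)
        upper = np.percentile(sims, 100 - tail, axis=0)
        if scalar:
            return float(lower[0]), float(upper[0])
        return lower, upper

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary table of coefficients and diagnostics."""
        names = ["b0", "b1", "b2"][: len(self.params)]
        lines = [
            f"Tree biomass model: {self.component}, form f({self.form})",
            f"  n = {self.n_used}  (outliers removed: {self.n_outliers_removed})",
            f"  variance exponent lambda = {self.lambda_:.4f}",
            "",
            f"  {'coef':>4} {'estimate':>12} {'std err':>10} {'p-value':>10}",
        ]
        for name, b, se, p in zip(names, self.params, self.bse, self.pvalues):
            lines.append(f"  {name:>4} {b:>12.6g} {se:>10.4g} {p:>10.3g}")
        lines += [
            "",
            f"  Breusch-Pagan chi2 = {self.bp_chi2:.4f}  (p = {self.bp_pvalue:.4f})",
            f"  AIC = {self.aic:.2f}   RSE = {self.rse:.5f}   MSE = {self.mse:.5f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        names = ["b0", "b1", "b2"][: len(self.params)]
        return {
            "component": self.component,
            "form": self.form,
            "params": dict(zip(names, self.params.tolist())),
            "bse": dict(zip(names, self.bse.tolist())),
            "pvalues": dict(zip(names, self.pvalues.tolist())),
            "cov": self.cov_params.tolist(),
            "lambda": self.lambda_,
            "alpha": None if np.isnan(self.alpha) else self.alpha,
            "bp_chi2": self.bp_chi2,
            "bp_pvalue": self.bp_pvalue,
            "aic": self.aic,
            "rse": self.rse,
            "mse": self.mse,
            "n_used": self.n_used,
            "n_outliers_removed": self.n_outliers_removed,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


@dataclass(frozen=True)
class PowerPredictor:
    """Lightweight deserialised power model, sufficient for prediction.

    Used where a full :class:`TreeBiomassResults` is not available, e.g.
    when models are reloaded from JSON for the stand pipeline.
    """

    component: str
    form: str
    params: np.ndarray
    cov_params: np.ndarray | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PowerPredictor":
        names = ["b0", "b1", "b2"]
        params = np.array([d["params"][k] for k in names if k in d["params"]])
        cov = np.array(d["cov"]) if d.get("cov") is not None else None
        return cls(d["component"], d["form"], params, cov)

    @classmethod
    def from_json(cls, path: str | Path) -> "PowerPredictor":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def predict(self, d0=None, h=None):
        out = _eval_form(self.form, self.params, d0, h)
        return float(out) if np.ndim(out) == 0 else out
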