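"""Parameter estimation for batch growth and lipid-production kinetics.

The estimators follow the scikit-learn protocol (``fit``/``predict``,
``get_params``/``set_params``, trailing-underscore fitted attributes) so
they compose with sklearn model selection, and the module-level
functions :func:`fit_logistic`, :func:`fit_luedeking_piret` and
:func:`fit_condition` are thin wrappers over them.

The pipeline mirrors standard bioprocess practice:

1. fit the logistic law to the biomass curve by nonlinear least squares,
   estimating (x0, k, xs) jointly;
2. with the growth parameters fixed, the integrated Luedeking-Piret
   model is *linear* in (alpha, beta), so the product curve is fitted by
   ordinary least squares on two known regressors;
3. diagnostics (R^2, mean absolute percent error) and the Gaden product
   class are attached to the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .dataset import TimeSeriesDataset
from .diagnostics import GadenClass, classify_gaden, percent_error, r_squared
from .kinetics import LogisticParams, LuedekingPiretParams

__all__ = [
    "NonIdentifiableError",
    "InsufficientDataError",
    "FitResult",
    "LogisticGrowthModel",
    "LuedekingPiretModel",
    "fit_logistic",
    "fit_luedeking_piret",
    "beta_stationary",
    "fit_condition",
]


class NonIdentifiableError(ValueError):
    """The data cannot pin down the model parameters (e.g. constant biomass)."""


class InsufficientDataError(ValueError):
    """Too few timepoints for the requested fit."""


@dataclass(frozen=True)
class FitResult:
    """Estimated kinetics for one culture condition, with diagnostics."""

    growth: LogisticParams
    prod: LuedekingPiretParams
    r2_growth: float
    r2_product: float
    pct_error_growth: float
    pct_error_product: float
    gaden_class: GadenClass
    condition_label: str = ""


def _as_times(X: ArrayLike) -> NDArray[np.float64]:
    t = np.asarray(X, dtype=float)
    if t.ndim == 2 and t.shape[1] == 1:
        t = t[:, 0]
    if t.ndim != 1:
        raise ValueError("expected a 1-D time vector or an (n, 1) column")
    return t


def _stable_logistic(t: NDArray[np.float64], x0: float, k: float, xs: float):
    # overflow-safe form of x0*e^{kt} / (1 - (x0/xs)(1 - e^{kt}))
    r = x0 / xs
    return x0 / (np.exp(-k * t) * (1.0 - r) + r)


def _log_growth_term(t: NDArray[np.float64], growth: LogisticParams):
    # ln[1 - (x0/xs)(1 - e^{kt})], evaluated without overflow
    r = growth.x0 / growth.xs
    return growth.k * t + np.log(np.exp(-growth.k * t) * (1.0 - r) + r)


class LogisticGrowthModel(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares fit of the logistic growth law.

    ``fit(X, y)`` takes sampling times (``X``, 1-D or a single column)
    and biomass concentrations (``y``, g/L) and estimates the initial
    biomass ``x0_``, rate constant ``k_`` and carrying capacity ``xs_``
    jointly, under positivity bounds.

    Initial guesses are deterministic and data-driven: ``x0`` starts at
    the first observation, ``xs`` at the largest, and ``k`` at the slope
    of ln(biomass) over the first half of the series, so repeated fits
    of the same data are bit-identical.

    Parameters
    ----------
    max_nfev : int
        Cap on least-squares function evaluations.

    Attributes
    ----------
    x0_, k_, xs_ : float
        Estimated parameters.
    growth_ : LogisticParams
        The same estimates as a parameter object.
    r2_ : float
        Coefficient of determination of the biomass fit.
    percent_error_ : float
        Mean absolute percent error of the biomass fit.
    """

    def __init__(self, max_nfev: int = 10_000):
        self.max_nfev = max_nfev

    def fit(self, X: ArrayLike, y: ArrayLike) -> "LogisticGrowthModel":
        t = _as_times(X)
        x = np.asarray(y, dtype=float)
        if x.shape != t.shape:
            raise ValueError("X and y must have the same number of samples")
        if np.unique(t).size < 4:
            raise InsufficientDataError(
                f"need >= 4 distinct timepoints, got {np.unique(t).size}"
            )
        if np.any(x < 0):
            raise ValueError("biomass observations must be nonnegative")
        order = np.argsort(t)
        t, x = t[order], x[order]
        if np.allclose(x, x[0]):
            raise NonIdentifiableError(
                "biomass is constant; logistic rate constant is unidentifiable"
            )
        if np.all(np.diff(x) < 0):
            raise NonIdentifiableError(
                "biomass is strictly decreasing; data are outside the growth "
                "regime of the logistic model"
            )

        x0_init = float(x[0]) if x[0] > 0 else float(x[x > 0].min())
        xs_init = float(x.max())
        half = max(2, t.size // 2)
        pos = x[:half] > 0  # zero readings carry no log-slope information
        if pos.sum() >= 2:
            k_init = float(np.polyfit(t[:half][pos], np.log(x[:half][pos]), 1)[0])
        else:
            k_init = np.nan
        if not np.isfinite(k_init) or k_init <= 0:
            k_init = 0.1
        p_init = (x0_init, k_init, max(xs_init, x0_init * (1 + 1e-6)))

        tiny = 1e-12
        try:
            popt, _ = curve_fit(
                _stable_logistic,
                t,
                x,
                p0=p_init,
                bounds=([tiny, tiny, tiny], [np.inf, np.inf, np.inf]),
                max_nfev=self.max_nfev,
            )
        except RuntimeError as exc:
            raise NonIdentifiableError(
                f"logistic fit did not converge (initial guesses x0={p_init[0]:g}, "
                f"k={p_init[1]:g}, xs={p_init[2]:g}): {exc}"
            ) from exc
        x0_hat, k_hat, xs_hat = map(float, popt)
        if x0_hat >= xs_hat:
            raise NonIdentifiableError(
                f"fitted x0={x0_hat:g} >= xs={xs_hat:g}: no growth to identify k"
            )
        self.x0_, self.k_, self.xs_ = x0_hat, k_hat, xs_hat
        self.growth_ = LogisticParams(x0=x0_hat, k=k_hat, xs=xs_hat)
        pred = _stable_logistic(t, *popt)
        self.r2_ = r_squared(x, pred)
        self.percent_error_ = percent_error(x, pred)
        self.n_features_in_ = 1
        return self

    def predict(self, X: ArrayLike) -> NDArray[np.float64]:
        check_is_fitted(self, "growth_")
        return _stable_logistic(_as_times(X), self.x0_, self.k_, self.xs_)


class LuedekingPiretModel(RegressorMixin, BaseEstimator):
    """Least-squares fit of the integrated Luedeking-Piret product model.

    With the logistic growth parameters held fixed, the product increase
    since the first observation is linear in (alpha, beta):

        P(t) - P(t_ref) = alpha * [x(t) - x(t_ref)]
                        + beta * (xs/k) * [ln D(t) - ln D(t_ref)]

    with D(t) = 1 - (x0/xs)(1 - e^{kt}).  ``fit`` solves this by
    ordinary least squares with no intercept, then clips the estimates
    at zero to respect the model's sign convention.

    Parameters
    ----------
    growth : LogisticParams or fitted LogisticGrowthModel
        Growth kinetics; must be supplied before ``fit``.
    """

    def __init__(self, growth: LogisticParams | LogisticGrowthModel | None = None):
        self.growth = growth

    def _growth_params(self) -> LogisticParams:
        g = self.growth
        if isinstance(g, LogisticGrowthModel):
            check_is_fitted(g, "growth_")
            return g.growth_
        if isinstance(g, LogisticParams):
            return g
        raise ValueError(
            "growth must be a LogisticParams or a fitted LogisticGrowthModel"
        )

    def fit(self, X: ArrayLike, y: ArrayLike) -> "LuedekingPiretModel":
        growth = self._growth_params()
        t = _as_times(X)
        p = np.asarray(y, dtype=float)
        if p.shape != t.shape:
            raise ValueError("X and y must have the same number of samples")
        if np.any(p < 0):
            raise ValueError("product observations must be nonnegative")
        order = np.argsort(t)
        t, p = t[order], p[order]
        if t.size - 1 < 3:
            raise InsufficientDataError(
                f"need >= 3 timepoints after the first, got {max(t.size - 1, 0)}"
            )

        x_t = _stable_logistic(t, growth.x0, growth.k, growth.xs)
        log_t = _log_growth_term(t, growth)
        g1 = x_t - x_t[0]
        g2 = (growth.xs / growth.k) * (log_t - log_t[0])
        design = np.column_stack([g1[1:], g2[1:]])
        if np.linalg.matrix_rank(design, tol=1e-10 * max(1.0, np.abs(design).max())) < 2:
            raise NonIdentifiableError(
                "product regressors are collinear on this time grid; "
                "alpha and beta cannot be separated"
            )
        coef, *_ = np.linalg.lstsq(design, p[1:] - p[0], rcond=None)
        alpha_hat = float(max(coef[0], 0.0))
        beta_hat = float(max(coef[1], 0.0))

        # reference anchoring: p at the first grid point
        self._t_ref_ = float(t[0])
        self._x_ref_ = float(x_t[0])
        self._log_ref_ = float(log_t[0])
        self._p_ref_ = float(p[0])
        self.alpha_, self.beta_ = alpha_hat, beta_hat
        # equivalent initial product concentration at t = 0
        p0_hat = self._p_ref_ - alpha_hat * (self._x_ref_ - growth.x0) - beta_hat * (
            growth.xs / growth.k
        ) * self._log_ref_
        self.p0_ = float(max(p0_hat, 0.0))
        self.prod_ = LuedekingPiretParams(alpha=alpha_hat, beta=beta_hat, p0=self.p0_)
        self._growth_fixed_ = growth
        pred = self.predict(t)
        self.r2_ = r_squared(p, pred) if np.ptp(p) > 0 else 1.0
        self.percent_error_ = (
            percent_error(p, pred) if np.any(p != 0) else 0.0
        )
        self.n_features_in_ = 1
        return self

    def predict(self, X: ArrayLike) -> NDArray[np.float64]:
        check_is_fitted(self, "prod_")
        growth = self._growth_fixed_
        t = _as_times(X)
        x_t = _stable_logistic(t, growth.x0, growth.k, growth.xs)
        log_t = _log_growth_term(t, growth)
        return (
            self._p_ref_
            + self.alpha_ * (x_t - self._x_ref_)
            + self.beta_ * (growth.xs / growth.k) * (log_t - self._log_ref_)
        )


def fit_logistic(data: TimeSeriesDataset) -> tuple[LogisticParams, float, float]:
    """Fit the logistic growth law to a dataset's biomass curve.

    Returns ``(params, r_squared, percent_error)``.
    """
    model = LogisticGrowthModel().fit(data.times, data.biomass)
    return model.growth_, model.r2_, model.percent_error_


def fit_luedeking_piret(
    data: TimeSeriesDataset, growth: LogisticParams
) -> tuple[LuedekingPiretParams, float, float]:
    """Fit the Luedeking-Piret product law with growth parameters fixed.

    Returns ``(params, r_squared, percent_error)``.
    """
    if not data.has_product:
        raise ValueError("dataset has no product column")
    model = LuedekingPiretModel(growth=growth).fit(data.times, data.product)
    return model.prod_, model.r2_, model.percent_error_


def beta_stationary(
    data: TimeSeriesDataset,
    xs: float,
    rel_tol: float = 0.02,
    min_points: int = 3,
) -> float:
    """Estimate beta from the stationary phase alone.

    During stationary phase dx/dt ~ 0, so dp/dt = beta * xs and

        beta = (stationary-phase product slope) / xs.

    The stationary window is the trailing run of points whose biomass is
    within ``rel_tol`` (default 2%) of the maximum observed biomass; at
    least ``min_points`` such points are required.  The slope is the
    mean of the finite-difference slopes of the product over that window.
    """
    if not data.has_product:
        raise ValueError("dataset has no product column")
    if xs <= 0:
        raise ValueError("xs must be positive")
    x = data.biomass
    threshold = (1.0 - rel_tol) * x.max()
    in_window = x >= threshold
    # trailing contiguous run
    n_tail = 0
    for flag in in_window[::-1]:
        if not flag:
            break
        n_tail += 1
    if n_tail < min_points:
        raise NonIdentifiableError(
            f"no stationary window: only {n_tail} trailing point(s) within "
            f"{rel_tol:.0%} of the biomass maximum (need >= {min_points}); "
            "use the joint integrated-model fit instead"
        )
    t_win = data.times[-n_tail:]
    p_win = data.product[-n_tail:]
    slopes = np.diff(p_win) / np.diff(t_win)
    return float(slopes.mean() / xs)


def fit_condition(
    data: TimeSeriesDataset,
    gaden_tol: float = 1e-6,
    condition_label: str | None = None,
) -> FitResult:
    """Run the full estimation pipeline on one condition's dataset.

    Fits the biomass curve (logistic), then the product curve
    (Luedeking-Piret with growth fixed), computes diagnostics, and
    assigns the Gaden product class from the estimated (alpha, beta).
    """
    if not data.has_product:
        raise ValueError("dataset has no product column; cannot run full pipeline")
    growth, r2_g, err_g = fit_logistic(data)
    prod, r2_p, err_p = fit_luedeking_piret(data, growth)
    gaden = classify_gaden(prod.alpha, prod.beta, tol=gaden_tol)
    return FitResult(
        growth=growth,
        prod=prod,
        r2_growth=r2_g,
        r2_product=r2_p,
        pct_error_growth=err_g,
        pct_error_product=err_p,
        gaden_class=gaden,
        condition_label=(
            condition_label if condition_label is not None else data.condition_label
        ),
    )
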