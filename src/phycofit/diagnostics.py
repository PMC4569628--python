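"""Fit diagnostics: percent error, coefficient of determination, Gaden class."""

from __future__ import annotations

import enum
import logging

import numpy as np
from numpy.typing import ArrayLike

__all__ = ["GadenClass", "percent_error", "r_squared", "classify_gaden"]

logger = logging.getLogger(__name__)


class GadenClass(enum.Enum):
    """Gaden's classification of fermentation products by their coupling
    to growth: Class I fully growth-associated (beta = 0), Class II
    partially associated (alpha != 0 and beta != 0), Class III
    non-growth-associated (alpha = 0)."""

    I = "I"
    II = "II"
    III = "III"

    def __str__(self) -> str:  # serialize as the bare roman numeral
        return self.value


def percent_error(observed: ArrayLike, predicted: ArrayLike) -> float:
    """Mean absolute relative deviation, in percent.

    Averages |(obs - pred) / obs| * 100 over timepoints.  Points where
    the observation is exactly zero carry an undefined relative error
    and are excluded from the mean (a debug message records how many).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(
            f"observed and predicted lengths differ: {obs.shape} vs {pred.shape}"
        )
    nonzero = obs != 0
    n_dropped = int(obs.size - nonzero.sum())
    if n_dropped:
        logger.debug(
            "percent_error: excluding %d zero-valued observation(s)", n_dropped
        )
    if not nonzero.any():
        raise ValueError("all observations are zero; percent error undefined")
    rel = np.abs((obs[nonzero] - pred[nonzero]) / obs[nonzero])
    return float(rel.mean() * 100.0)


def r_squared(observed: ArrayLike, predicted: ArrayLike) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot about the observed mean."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(
            f"observed and predicted lengths differ: {obs.shape} vs {pred.shape}"
        )
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed series has zero variance; R^2 undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def classify_gaden(alpha: float, beta: float, tol: float = 1e-6) -> GadenClass:
    """Assign the Gaden product class from Luedeking-Piret coefficients.

    A coefficient is treated as zero when its magnitude is <= ``tol``
    (default 1e-6, in the coefficients' own units).  Both coefficients
    zero means no product is formed at all and is an error.
    """
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be nonnegative")
    if tol < 0:
        raise ValueError("tol must be nonnegative")
    alpha_zero = abs(alpha) <= tol
    beta_zero = abs(beta) <= tol
    if alpha_zero and beta_zero:
        raise ValueError(
            f"alpha={alpha} and beta={beta} are both within tol={tol} of zero: "
            "no product formation to classify"
        )
    if alpha_zero:
        return GadenClass.III
    if beta_zero:
        return GadenClass.I
    return GadenClass.II
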