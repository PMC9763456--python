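"""Weight and biomass estimation models.

Weights that cannot be read straight off a CT volume (copra weight, husk
biomass, ...) are regressed on image traits.  Six single-predictor model
families are supported -- linear, power, exponential, logarithmic,
quadratic and logistic -- fitted by least squares (log-linearized where
that is the standard estimator) and compared by adjusted R^2; liquids are
converted volume -> weight directly through a density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FAMILIES",
    "RegressionModel",
    "fit_model",
    "select_model",
    "accuracy_metrics",
    "liquid_weight",
]

FAMILIES = ("linear", "power", "exponential", "logarithmic", "quadratic", "logistic")

#: parameter count per family (used by the adjusted R^2 penalty)
_N_PARAMS = {
    "linear": 2,
    "power": 2,
    "exponential": 2,
    "logarithmic": 2,
    "quadratic": 3,
    "logistic": 3,
}


@dataclass
class RegressionModel:
    """A fitted trait -> target model with its goodness-of-fit metrics."""

    family: str
    predictors: list[str]
    coefficients: np.ndarray
    n: int
    p: int
    r2: float
    adjusted_r2: float
    mape: float
    rmse: float
    _predict_fn: object = field(repr=False, default=None)

    def predict(self, x) -> np.ndarray:
        return self._predict_fn(np.asarray(x, dtype=float))

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "predictors": self.predictors,
            "coefficients": [float(c) for c in self.coefficients],
            "n": self.n,
            "p": self.p,
            "r2": self.r2,
            "adjusted_r2": self.adjusted_r2,
            "mape": self.mape,
            "rmse": self.rmse,
        }


def accuracy_metrics(pred, true) -> tuple[float, float, float, float]:
    """(R^2, adjusted R^2 with p=1, MAPE %, RMSE).

    R^2 = 1 - SSres/SStot; MAPE = mean(|pred-true|/|true|) * 100;
    RMSE = sqrt(mean((pred-true)^2)).
    """
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape or pred.size < 2:
        raise ValueError("pred and true must share a length >= 2")
    sstot = float(np.sum((true - true.mean()) ** 2))
    if sstot == 0:
        raise ValueError("R^2 undefined: zero variance in true values")
    if np.any(true == 0):
        raise ValueError("MAPE undefined: true contains zeros")
    ssres = float(np.sum((pred - true) ** 2))
    r2 = 1.0 - ssres / sstot
    n = pred.size
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    mape = float(np.mean(np.abs(pred - true) / np.abs(true))) * 100.0
    rmse = float(np.sqrt(np.mean((pred - true) ** 2)))
    return r2, adj, mape, rmse


def _metrics_for(family, coef, predict, x, y):
    yhat = predict(x)
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0:
        raise ValueError("target has zero variance")
    r2 = 1.0 - float(np.sum((yhat - y) ** 2)) / sstot
    n = len(y)
    p = _N_PARAMS[family] - 1  # slope-like parameters, intercept excluded
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(yhat - y) / np.abs(y)
        rel = rel[np.isfinite(rel)]
    mape = float(np.mean(rel)) * 100.0 if rel.size else float("nan")
    rmse = float(np.sqrt(np.mean((yhat - y) ** 2)))
    return r2, adj, mape, rmse


def fit_model(
    x, y, family: str, predictor_name: str = "x"
) -> RegressionModel:
    """Least-squares fit of one model family to (x, y).

    power/exponential/logarithmic are linearized through logs (requiring
    positive data where the log applies); quadratic is a polynomial fit;
    logistic y = L / (1 + exp(-k (x - x0))) uses bounded nonlinear least
    squares initialized from the data range.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = len(x)
    if n != len(y):
        raise ValueError("x and y lengths differ")
    if n <= _N_PARAMS[family] + 1:
        raise ValueError(f"need n > p+1 = {_N_PARAMS[family] + 1} observations")

    if family in ("power", "logarithmic") and np.any(x <= 0):
        bad = np.nonzero(x <= 0)[0]
        raise ValueError(f"{family} fit requires x > 0 (rows {bad[:5].tolist()})")
    if family in ("power", "exponential") and np.any(y <= 0):
        bad = np.nonzero(y <= 0)[0]
        raise ValueError(f"{family} fit requires y > 0 (rows {bad[:5].tolist()})")

    if family == "linear":
        A = np.column_stack([x, np.ones(n)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        a, b = coef

        def predict(t, a=a, b=b):
            return a * t + b

        coefs = np.array([a, b])
    elif family == "quadratic":
        coefs = np.polyfit(x, y, 2)

        def predict(t, c=coefs):
            return np.polyval(c, t)

    elif family == "logarithmic":
        A = np.column_stack([np.log(x), np.ones(n)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        a, b = coef

        def predict(t, a=a, b=b):
            return a * np.log(t) + b

        coefs = np.array([a, b])
    elif family == "power":
        A = np.column_stack([np.log(x), np.ones(n)])
        coef, *_ = np.linalg.lstsq(A, np.log(y), rcond=None)
        b, loga = coef
        a = np.exp(loga)

        def predict(t, a=a, b=b):
            return a * np.power(t, b)

        coefs = np.array([a, b])
    elif family == "exponential":
        A = np.column_stack([x, np.ones(n)])
        coef, *_ = np.linalg.lstsq(A, np.log(y), rcond=None)
        b, loga = coef
        a = np.exp(loga)

        def predict(t, a=a, b=b):
            return a * np.exp(b * t)

        coefs = np.array([a, b])
    else:  # logistic
        def logistic(t, L, k, x0):
            return L / (1.0 + np.exp(-np.clip(k * (t - x0), -500, 500)))

        span = np.ptp(x) or 1.0
        p0 = [float(y.max()) * 1.05, 4.0 / span, float(np.median(x))]
        bounds = ([1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf])
        try:
            coefs, _ = curve_fit(logistic, x, y, p0=p0, bounds=bounds, maxfev=20000)
        except RuntimeError as exc:
            raise ValueError(f"logistic fit did not converge: {exc}") from exc

        def predict(t, c=coefs):
            return logistic(t, *c)

    if np.linalg.matrix_rank(np.column_stack([x, np.ones(n)])) < 2:
        raise ValueError("singular design: predictor is constant")

    r2, adj, mape, rmse = _metrics_for(family, coefs, predict, x, y)
    return RegressionModel(
        family=family,
        predictors=[predictor_name],
        coefficients=np.asarray(coefs, dtype=float),
        n=n,
        p=_N_PARAMS[family] - 1,
        r2=r2,
        adjusted_r2=adj,
        mape=mape,
        rmse=rmse,
        _predict_fn=predict,
    )


def select_model(candidates) -> RegressionModel:
    """Best candidate by adjusted R^2; ties prefer fewer parameters, then
    the canonical family order."""
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate models")
    return min(
        candidates,
        key=lambda m: (-m.adjusted_r2, m.p, FAMILIES.index(m.family)),
    )


def liquid_weight(volume_mm3: float, density_g_per_ml: float = 1.0) -> float:
    """Direct weight of a liquid compartment: volume (mL) x density."""
    if density_g_per_ml <= 0:
        raise ValueError("density must be positive")
    return volume_mm3 / 1000.0 * density_g_per_ml
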