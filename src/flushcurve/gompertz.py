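"""Gompertz growth-curve primitives.

The Gompertz curve

    y(t) = A * exp(-exp(B - C * t))

is an asymmetric sigmoid rising from ~0 to the upper asymptote ``A`` (maximum
cumulative harvest of a flush, in stems), with growth-rate parameter ``B``
(dimensionless) and horizontal-shift rate ``C`` (per day).  Its single
inflection point lies at t = B/C, where y = A/e.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["GompertzParams", "gompertz", "gompertz_gradient", "efron_r2"]


@dataclass(frozen=True)
class GompertzParams:
    """Parameters of a single Gompertz curve.

    A : upper asymptote, stems (> 0)
    B : growth-rate parameter, dimensionless
    C : horizontal-shift rate, per day (> 0)
    """

    A: float
    B: float
    C: float

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise ValueError(f"asymptote A must be positive, got {self.A}")
        if not self.C > 0:
            raise ValueError(f"shift rate C must be positive, got {self.C}")

    @property
    def inflection_day(self) -> float:
        """Day of maximum growth rate, where the curve passes A/e."""
        return self.B / self.C

    def predict(self, t) -> np.ndarray:
        return gompertz(t, self.A, self.B, self.C)


def gompertz(t, A: float, B: float, C: float) -> np.ndarray:
    """Evaluate A * exp(-exp(B - C*t)) elementwise.

    Monotone increasing in ``t`` (for C > 0) with supremum ``A``.
    """
    t = np.asarray(t, dtype=float)
    return A * np.exp(-np.exp(B - C * t))


def gompertz_gradient(t, A: float, B: float, C: float) -> np.ndarray:
    """Gradient of the Gompertz curve w.r.t. (A, B, C), shape (len(t), 3)."""
    t = np.asarray(t, dtype=float)
    g = np.exp(B - C * t)
    core = np.exp(-g)
    dA = core
    dB = -A * core * g
    dC = A * core * g * t
    return np.column_stack([dA, dB, dC])


def efron_r2(observed, fitted) -> float:
    """Efron's R-squared: 1 - SSE / SST.

    ``1 - sum((y - yhat)^2) / sum((y - ybar)^2)``; applicable to any
    predictor, not only least-squares fits.  Returns NaN (with a warning)
    when the observed values have zero variance, where the measure is
    undefined.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(fitted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: observed {y.shape} vs fitted {yhat.shape}")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        warnings.warn("observed values have zero variance; Efron R^2 undefined")
        return float("nan")
    sse = float(np.sum((y - yhat) ** 2))
    return 1.0 - sse / sst
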