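"""SPAD chlorophyll calibration: prototype curve fits and published models.

A calibration model maps the canopy-mean value of one vegetation index to
the plant's mean SPAD reading (the unitless output of a hand-held
chlorophyll meter).  Four prototype functional forms are supported:

    M1  linear       SPAD = a*x + b
    M2  quadratic    SPAD = a*x^2 + b*x + c
    M3  exponential  SPAD = c * 10^(k*x)
    M4  power        SPAD = c * x^k      (requires x > 0)

Goodness of fit is reported as R^2 = 1 - SS_res/SS_tot and
RMSE = sqrt(SS_res/n) (denominator n, not n - p).  M3 and M4 are fitted by
nonlinear least squares initialized from the log-linearized ordinary
least-squares solution.  A registry of published calibration equations
(one per index, fitted on a fused multiview canopy model) ships with the
module and is served by :func:`paper_model`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["SpadModel", "FitResult", "fit", "predict", "evaluate", "paper_model",
           "PROTOTYPES"]

PROTOTYPES = ("M1", "M2", "M3", "M4")
_N_COEF = {"M1": 2, "M2": 3, "M3": 2, "M4": 2}


class UndefinedR2Error(ValueError):
    """SS_tot is zero (constant y); R^2 undefined."""


@dataclass(frozen=True)
class SpadModel:
    """One fitted or published SPAD calibration curve.

    ``coefficients`` ordering: M1 (slope, intercept); M2 (a, b, c) for
    a*x^2 + b*x + c; M3 (c, k) for c*10^(k*x); M4 (c, k) for c*x^k.
    """

    prototype: str
    coefficients: tuple[float, ...]
    index_name: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.prototype not in PROTOTYPES:
            raise ValueError(f"unknown prototype {self.prototype!r}")
        object.__setattr__(
            self, "coefficients", tuple(float(c) for c in self.coefficients)
        )
        if len(self.coefficients) != _N_COEF[self.prototype]:
            raise ValueError(
                f"{self.prototype} needs {_N_COEF[self.prototype]} coefficients"
            )
        if self.prototype in ("M3", "M4") and self.coefficients[0] <= 0:
            raise ValueError(f"{self.prototype} leading coefficient must be > 0")

    def to_json(self, **extra) -> str:
        return json.dumps(
            {
                "prototype": self.prototype,
                "coefficients": list(self.coefficients),
                "index_name": self.index_name,
                "metadata": self.metadata,
                **extra,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SpadModel":
        d = json.loads(text)
        return cls(
            prototype=d["prototype"],
            coefficients=tuple(d["coefficients"]),
            index_name=d.get("index_name", ""),
            metadata=d.get("metadata", {}),
        )


@dataclass(frozen=True)
class FitResult:
    model: SpadModel
    r_squared: float
    rmse: float

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")
        if self.r_squared > 1 + 1e-12:
            raise ValueError("r_squared cannot exceed 1")


def predict(model: SpadModel, x) -> np.ndarray | float:
    """Evaluate the prototype at x (M4 requires x > 0)."""
    xv = np.asarray(x, dtype=float)
    c = model.coefficients
    if model.prototype == "M1":
        y = c[0] * xv + c[1]
    elif model.prototype == "M2":
        y = c[0] * xv**2 + c[1] * xv + c[2]
    elif model.prototype == "M3":
        y = c[0] * 10.0 ** (c[1] * xv)
    else:  # M4
        if np.any(xv <= 0):
            raise ValueError("power-law model requires x > 0")
        y = c[0] * xv ** c[1]
    return float(y) if np.ndim(x) == 0 else y


def _goodness(y: np.ndarray, yhat: np.ndarray, pearson: bool = False):
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedR2Error("constant y: SS_tot = 0, R^2 undefined")
    if pearson:
        r2 = float(np.corrcoef(y, yhat)[0, 1] ** 2)
    else:
        r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(ss_res / len(y)))
    return r2, rmse


def fit(
    x: np.ndarray,
    y: np.ndarray,
    prototype: str,
    index_name: str = "",
    r2_mode: str = "ss",
) -> FitResult:
    """Least-squares fit of one prototype to (index, SPAD) pairs.

    M1/M2 are ordinary polynomial least squares.  M3/M4 are nonlinear least
    squares on the original scale, initialized from the log-linearized OLS
    solution (so noiseless data is recovered to machine precision while
    noisy fits minimize the untransformed residual).  ``r2_mode`` selects
    ``"ss"`` (1 - SS_res/SS_tot, default) or ``"pearson"`` (squared
    correlation of y with fitted values).
    """
    if prototype not in PROTOTYPES:
        raise ValueError(f"unknown prototype {prototype!r}")
    xv = np.asarray(x, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    if xv.shape != yv.shape:
        raise ValueError("x and y must have the same length")
    n = len(xv)
    if n < _N_COEF[prototype] + 1:
        raise ValueError(
            f"need at least {_N_COEF[prototype] + 1} points for {prototype}"
        )
    if np.ptp(yv) == 0:
        raise UndefinedR2Error("constant y: SS_tot = 0, R^2 undefined")

    if prototype == "M1":
        coef = tuple(np.polyfit(xv, yv, 1))
    elif prototype == "M2":
        coef = tuple(np.polyfit(xv, yv, 2))
    elif prototype == "M3":
        if np.any(yv <= 0):
            raise ValueError("exponential fit requires y > 0")
        k0, logc0 = np.polyfit(xv, np.log10(yv), 1)
        popt, _ = curve_fit(
            lambda t, c, k: c * 10.0 ** (k * t),
            xv,
            yv,
            p0=[10.0**logc0, k0],
            maxfev=10000,
        )
        coef = (float(popt[0]), float(popt[1]))
    else:  # M4
        if np.any(xv <= 0):
            raise ValueError("power fit requires x > 0")
        if np.any(yv <= 0):
            raise ValueError("power fit requires y > 0")
        k0, logc0 = np.polyfit(np.log10(xv), np.log10(yv), 1)
        popt, _ = curve_fit(
            lambda t, c, k: c * t**k, xv, yv, p0=[10.0**logc0, k0], maxfev=10000
        )
        coef = (float(popt[0]), float(popt[1]))

    model = SpadModel(prototype=prototype, coefficients=coef, index_name=index_name)
    r2, rmse = _goodness(yv, np.asarray(predict(model, xv)), r2_mode == "pearson")
    return FitResult(model=model, r_squared=r2, rmse=rmse)


def evaluate(
    model: SpadModel, x: np.ndarray, y: np.ndarray, r2_mode: str = "ss"
) -> tuple[float, float]:
    """R^2 and RMSE of the model on the given data (usable on held-out sets)."""
    xv = np.asarray(x, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    if len(xv) < 2:
        raise ValueError("need at least two points")
    return _goodness(yv, np.asarray(predict(model, xv)), r2_mode == "pearson")


# Published calibration equations for the fused multiview (3DROI) canopy
# model, one per vegetation index, with their printed fit diagnostics kept
# as metadata.  Coefficients are stored exactly as printed.
_PUBLISHED_TABLE: dict[str, tuple[str, tuple[float, ...], float, float]] = {
    "NDVI": ("M2", (154.8, -77.053, 43.256), 0.8670, 1.2916),
    "GNDVI": ("M3", (14.998, 2.4631), 0.9414, 0.8725),
    "NDVIR": ("M4", (120.28, 0.5542), 0.9253, 0.9940),
    "CIG": ("M3", (24.001, 0.333), 0.9443, 0.8508),
    "RCIG": ("M2", (-18.37, 58.963, 23.433), 0.9023, 1.1066),
    "NG": ("M2", (-2311.2, 762.19, -9.1868), 0.9188, 1.008),
    "NR": ("M3", (122.99, -5.537), 0.8071, 1.5918),
    "RVI": ("M2", (1.3041, -2.805, 35.654), 0.9019, 1.1091),
    "GRVI": ("M2", (5.9953, -19.913, 51.704), 0.9408, 0.8616),
}


def paper_model(index_name: str) -> SpadModel:
    """Published SPAD calibration for one index (immutable registry copy)."""
    if index_name not in _PUBLISHED_TABLE:
        raise KeyError(
            f"no published model for {index_name!r}; choose from "
            f"{sorted(_PUBLISHED_TABLE)}"
        )
    proto, coef, r2, rmse = _PUBLISHED_TABLE[index_name]
    return SpadModel(
        prototype=proto,
        coefficients=coef,
        index_name=index_name,
        metadata={"published_r2": r2, "published_rmse": rmse, "source": "3DROI"},
    )
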