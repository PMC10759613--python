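"""Standard-curve fitting and inverse prediction for multiplex cytokine plates.

Two calibration models are supported, matching common plate-reader practice
for chemiluminescent multiplex immunoassays:

* ``poly2`` — second-order polynomial, y = b0 + b1*x + b2*x^2
* ``logistic5p`` — five-parameter logistic,
  y = d + (a - d) / (1 + (x/c)^b)^g,
  with ``a`` the upper asymptote, ``d`` the lower asymptote, ``c`` the
  inflection concentration, ``b`` the slope and ``g`` the asymmetry
  (``g = 1`` recovers the symmetric 4PL). The 5PL may be fitted with 1/y
  weighting, which down-weights high-signal wells so that the relative error
  of back-calculated concentrations is balanced across the curve.

Sample concentrations are obtained by inverting the fitted curve; signals
outside the attainable range are flagged (above-top vs below-bottom) rather
than imputed, and duplicate wells are averaged on the concentration scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "StandardCurve",
    "CurveFitError",
    "CurveRangeError",
    "AmbiguousInversionError",
    "fit_poly2",
    "fit_5pl",
    "invert_curve",
    "back_calculate",
    "average_duplicates",
]


class CurveFitError(ValueError):
    """Raised when a standard curve cannot be fitted from the given wells."""


class CurveRangeError(ValueError):
    """Signal outside the curve's attainable range.

    ``side`` is ``"above_top"`` or ``"below_bottom"``.
    """

    def __init__(self, message: str, side: str):
        super().__init__(message)
        self.side = side


class AmbiguousInversionError(ValueError):
    """Two admissible poly2 roots fall inside the calibrated range."""


def _logistic5p(x, a, d, c, b, g):
    """y = d + (a - d)/(1 + (x/c)^b)^g.

    With b > 0 the curve runs from a at zero dose down to d; with b < 0 it
    rises from d at zero dose to a — the usual orientation for a sandwich
    immunoassay where a is the saturating (upper) signal.
    """
    with np.errstate(divide="ignore", over="ignore"):
        return d + (a - d) / (1.0 + (np.asarray(x, float) / c) ** b) ** g


@dataclass
class StandardCurve:
    """A fitted calibration curve with its inverse-prediction support."""

    model: str  # "poly2" | "logistic5p"
    params: dict[str, float]
    weighting: str = "none"  # "none" | "inverse_y"
    calibrated_range: tuple[float, float] = (0.0, np.inf)
    fit_diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in ("poly2", "logistic5p"):
            raise CurveFitError(f"unknown model {self.model!r}")
        if self.weighting not in ("none", "inverse_y"):
            raise CurveFitError(f"unknown weighting {self.weighting!r}")
        lo, hi = self.calibrated_range
        if not lo < hi:
            raise CurveFitError("calibrated_range must be a nonempty interval")
        if self.model == "logistic5p":
            if not (self.params["c"] > 0 and self.params["g"] > 0):
                raise CurveFitError("logistic5p requires c > 0 and g > 0")
        else:
            missing = {"b0", "b1", "b2"} - set(self.params)
            if missing:
                raise CurveFitError(f"poly2 missing coefficients {missing}")

    # -- evaluation -------------------------------------------------------
    def evaluate(self, conc):
        """Predicted signal at the given concentration(s)."""
        x = np.asarray(conc, dtype=float)
        if self.model == "poly2":
            p = self.params
            out = p["b0"] + p["b1"] * x + p["b2"] * x**2
        else:
            out = _logistic5p(x, **{k: self.params[k] for k in "adcbg"})
        return out if out.ndim else float(out)

    def signal_range(self) -> tuple[float, float]:
        """Attainable (min, max) signal over the calibrated range."""
        lo, hi = self.calibrated_range
        if self.model == "logistic5p":
            ends = self.evaluate(np.array([lo, hi]))
            return float(min(ends)), float(max(ends))
        grid = np.linspace(lo, hi, 513)
        vals = self.evaluate(grid)
        return float(vals.min()), float(vals.max())

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": dict(self.params),
            "weighting": self.weighting,
            "calibrated_range": list(self.calibrated_range),
            "fit_diagnostics": self.fit_diagnostics,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "StandardCurve":
        return cls(
            model=payload["model"],
            params=dict(payload["params"]),
            weighting=payload.get("weighting", "none"),
            calibrated_range=tuple(payload["calibrated_range"]),
            fit_diagnostics=payload.get("fit_diagnostics", {}),
        )

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def _residual_summary(residuals: np.ndarray) -> dict:
    return {
        "rss": float(np.sum(residuals**2)),
        "max_abs": float(np.max(np.abs(residuals))) if residuals.size else 0.0,
        "n_points": int(residuals.size),
    }


def fit_poly2(concentrations, signals) -> StandardCurve:
    """Least-squares second-order polynomial standard curve.

    Interpolates exactly when given exactly three distinct concentrations.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(signals, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CurveFitError("concentrations and signals must be 1-D and equal length")
    if np.unique(x).size < 3:
        raise CurveFitError(
            "poly2 requires at least 3 distinct concentrations "
            f"(got {np.unique(x).size}); the design matrix is rank-deficient"
        )
    coeffs = np.polynomial.polynomial.polyfit(x, y, deg=2)
    b0, b1, b2 = (float(v) for v in coeffs)
    residuals = y - (b0 + b1 * x + b2 * x**2)
    return StandardCurve(
        model="poly2",
        params={"b0": b0, "b1": b1, "b2": b2},
        weighting="none",
        calibrated_range=(float(x.min()), float(x.max())),
        fit_diagnostics=_residual_summary(residuals),
    )


def _5pl_starts(x, y):
    """Multi-start initial guesses: asymptotes from the signal extremes,
    c from the signal-midpoint crossing, slope magnitudes in {0.5, 1, 2}
    signed by the data's orientation (rising signal needs b < 0), g = 1."""
    a0 = float(np.max(y))
    d0 = float(np.min(y))
    span = a0 - d0
    mid = d0 + span / 2.0
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    crossing = xs[np.argmin(np.abs(ys - mid))]
    c0 = float(crossing) if crossing > 0 else float(np.median(xs[xs > 0]))
    rising = np.corrcoef(xs, ys)[0, 1] > 0
    sign = -1.0 if rising else 1.0
    for b0 in (0.5, 1.0, 2.0):
        yield np.array(
            [a0 + 0.05 * span, max(d0 - 0.05 * span, 1e-6), c0, sign * b0, 1.0]
        )


def fit_5pl(concentrations, signals, weighting: str = "inverse_y") -> StandardCurve:
    """Five-parameter logistic standard curve via weighted least squares.

    With ``weighting="inverse_y"`` the objective is sum(w_i*(y_i - f(x_i))^2)
    with w_i = 1/y_i, the conventional immunoassay weighting; all signals must
    then be positive. Multi-start initialization; the best converged start is
    kept and convergence diagnostics are attached.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(signals, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CurveFitError("concentrations and signals must be 1-D and equal length")
    if np.unique(x).size < 6:
        raise CurveFitError("logistic5p requires >= 6 distinct concentrations")
    if weighting == "inverse_y" and np.any(y <= 0):
        raise CurveFitError(
            "inverse_y weighting requires strictly positive signals"
        )
    if np.any(x < 0):
        raise CurveFitError("concentrations must be >= 0")

    sqrt_w = 1.0 / np.sqrt(y) if weighting == "inverse_y" else np.ones_like(y)
    pos = x > 0

    def residual(theta):
        a, d, c, b, g = theta
        pred = _logistic5p(x, a, d, c, b, g)
        return sqrt_w * (pred - y)

    lo_bounds = [-np.inf, -np.inf, 1e-12, -np.inf, 1e-6]
    hi_bounds = [np.inf, np.inf, np.inf, np.inf, np.inf]
    best = None
    tried = []
    for start in _5pl_starts(x[pos], y[pos]):
        sol = least_squares(
            residual, start, bounds=(lo_bounds, hi_bounds),
            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20000,
        )
        tried.append(float(sol.cost))
        if best is None or sol.cost < best.cost:
            best = sol
    a, d, c, b, g = (float(v) for v in best.x)
    residuals = best.fun
    diagnostics = _residual_summary(residuals)
    diagnostics.update(
        {
            "converged": bool(best.success),
            "multi_start_costs": tried,
            "final_cost": float(best.cost),
        }
    )
    return StandardCurve(
        model="logistic5p",
        params={"a": a, "d": d, "c": c, "b": b, "g": g},
        weighting=weighting,
        calibrated_range=(float(x[pos].min()) if pos.any() else float(x.min()),
                          float(x.max())),
        fit_diagnostics=diagnostics,
    )


def invert_curve(curve: StandardCurve, signal: float) -> float:
    """Concentration in the calibrated range mapping to ``signal``.

    Raises :class:`CurveRangeError` for signals outside the attainable range
    (distinguishing above-top from below-bottom) and
    :class:`AmbiguousInversionError` when a poly2 curve admits two roots in
    range (non-monotone segment).
    """
    sig_lo, sig_hi = curve.signal_range()
    tol = 1e-9 * max(1.0, abs(sig_hi - sig_lo))
    if signal > sig_hi + tol:
        raise CurveRangeError(
            f"signal {signal} above attainable maximum {sig_hi}", "above_top"
        )
    if signal < sig_lo - tol:
        raise CurveRangeError(
            f"signal {signal} below attainable minimum {sig_lo}", "below_bottom"
        )
    signal = float(np.clip(signal, sig_lo, sig_hi))
    lo, hi = curve.calibrated_range

    if curve.model == "logistic5p":
        p = curve.params
        a, d, c, b, g = p["a"], p["d"], p["c"], p["b"], p["g"]
        # closed-form inverse of the 5PL on its monotone branch
        ratio = (a - d) / (signal - d)
        if ratio <= 0:
            raise CurveRangeError("signal outside the 5PL asymptotes", "below_bottom")
        base = ratio ** (1.0 / g) - 1.0
        if base <= 0:
            # signal at/above upper asymptote side; clamp to range end
            return lo if (a > d) == (b > 0) else hi
        return float(np.clip(c * base ** (1.0 / b), lo, hi))

    p = curve.params
    roots = np.roots([p["b2"], p["b1"], p["b0"] - signal])
    real = roots[np.abs(roots.imag) < 1e-9].real
    span = hi - lo
    admissible = np.unique(
        np.round(real[(real >= lo - 1e-9 * span) & (real <= hi + 1e-9 * span)], 12)
    )
    if admissible.size == 0:
        # numerically at the range edge
        side = "above_top" if signal >= sig_hi - tol else "below_bottom"
        raise CurveRangeError(
            f"no poly2 root in the calibrated range for signal {signal}", side
        )
    if admissible.size > 1:
        raise AmbiguousInversionError(
            f"two admissible poly2 roots {admissible.tolist()} in the "
            "calibrated range; restrict the range to a monotone segment"
        )
    return float(np.clip(admissible[0], lo, hi))


def back_calculate(curve: StandardCurve, signals) -> tuple[np.ndarray, list[str | None]]:
    """Vector inverse prediction; out-of-range wells become NaN with a flag."""
    signals = np.asarray(signals, dtype=float)
    concs = np.full(signals.shape, np.nan)
    flags: list[str | None] = [None] * signals.size
    for i, s in enumerate(signals.ravel()):
        if np.isnan(s):
            flags[i] = "missing"
            continue
        try:
            concs.ravel()[i] = invert_curve(curve, float(s))
        except CurveRangeError as err:
            flags[i] = err.side
        except AmbiguousInversionError:
            flags[i] = "ambiguous"
    return concs, flags


def average_duplicates(readings) -> tuple[float, int]:
    """Arithmetic mean of 1-4 non-missing back-calculated concentrations.

    Returns ``(mean, n_wells)``; all-missing input yields ``(nan, 0)``.
    """
    vals = np.asarray(readings, dtype=float)
    if vals.ndim != 1 or not 1 <= vals.size <= 4:
        raise ValueError("expected 1-4 readings per sample")
    ok = ~np.isnan(vals)
    if not ok.any():
        return float("nan"), 0
    return float(vals[ok].mean()), int(ok.sum())
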