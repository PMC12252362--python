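"""Four-parameter logistic (4PL) dose-response calibration.

Maps the avePix readout to analyte concentration via

    y(x) = D + (A - D) / (1 + (x / C)^B)

with A the asymptote at zero dose, D the asymptote at infinite dose, C
the inflection concentration (dose units) and B the slope factor.  Both
sandwich (signal rises with dose) and competitive (signal falls) formats
are covered by the orientation of A/D and the sign of B; the
parameterization is degenerate under (A, D, B) -> (D, A, -B), which
leaves the curve unchanged.

Fitting is ordinary (optionally weighted) least squares with standard
robust starting values; the result object carries the estimates, their
standard errors, R^2 and a summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import ConfigError, FitError


@dataclass(frozen=True)
class FourPL:
    """4PL parameter set."""

    A: float
    D: float
    C: float
    B: float

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ConfigError(f"inflection concentration C must be > 0, got {self.C}")

    def predict(self, x) -> np.ndarray:
        """Model response at dose(s) x > 0."""
        x = np.asarray(x, dtype=np.float64)
        return self.D + (self.A - self.D) / (1.0 + (x / self.C) ** self.B)


def _four_pl(x, A, D, C, B):
    # the optimizer may probe C <= 0, where the power is undefined; the
    # resulting NaNs just steer it away from that region
    with np.errstate(invalid="ignore", divide="ignore"):
        return D + (A - D) / (1.0 + (x / C) ** B)


@dataclass(frozen=True)
class FourPLResult:
    """Fit result: estimates, uncertainties and goodness of fit."""

    model: FourPL
    r_squared: float
    stderr: np.ndarray = field(repr=False)
    cov: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)
    n_obs: int = 0

    def summary(self) -> str:
        names = ("A (zero-dose asymptote)", "D (infinite-dose asymptote)",
                 "C (inflection conc.)", "B (slope factor)")
        values = (self.model.A, self.model.D, self.model.C, self.model.B)
        lines = [
            "Four-parameter logistic fit",
            f"  observations: {self.n_obs}    R^2: {self.r_squared:.6f}",
            f"  {'parameter':<30}{'estimate':>14}{'std err':>12}",
        ]
        for name, val, se in zip(names, values, self.stderr):
            lines.append(f"  {name:<30}{val:>14.6g}{se:>12.3g}")
        return "\n".join(lines)


def fit_4pl(doses, signals, weights=None) -> FourPLResult:
    """Least-squares 4PL fit of mean signal vs dose.

    Parameters
    ----------
    doses : positive concentrations (at least 4 distinct values)
    signals : measured responses, one per dose
    weights : optional per-point weights, or the string "1/y2" for
        inverse-variance-style 1/y^2 weighting

    Starting values: A and D from the responses at the lowest/highest
    dose, C from the dose whose signal is nearest the half-range, B = 1
    (the A/D orientation encodes the response direction).
    """
    x = np.asarray(doses, dtype=np.float64)
    y = np.asarray(signals, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigError("doses and signals must be 1-D arrays of equal length")
    if np.any(x <= 0):
        raise ConfigError("all doses must be > 0")
    if not np.all(np.isfinite(y)):
        raise ConfigError("signals must be finite")
    if np.unique(x).size < 4:
        raise FitError(
            f"4PL needs at least 4 distinct doses, got {np.unique(x).size}"
        )
    order = np.argsort(x)
    a0 = float(y[order[0]])
    d0 = float(y[order[-1]])
    if a0 == d0:
        a0, d0 = float(y.min()), float(y.max())
    half = (a0 + d0) / 2.0
    c0 = float(x[np.argmin(np.abs(y - half))])
    p0 = (a0, d0, max(c0, x.min()), 1.0)

    sigma = None
    if weights is not None:
        if isinstance(weights, str):
            if weights != "1/y2":
                raise ConfigError(f"unknown weighting scheme {weights!r}")
            wts = 1.0 / np.maximum(np.abs(y), 1e-12) ** 2
        else:
            wts = np.asarray(weights, dtype=np.float64)
            if wts.shape != y.shape or np.any(wts <= 0):
                raise ConfigError("weights must be positive, one per observation")
        sigma = 1.0 / np.sqrt(wts)

    try:
        popt, pcov = curve_fit(
            _four_pl, x, y, p0=p0, sigma=sigma, absolute_sigma=False, maxfev=20000
        )
    except RuntimeError as exc:
        raise FitError(
            f"4PL fit did not converge (start {p0}, doses "
            f"[{x.min():g}, {x.max():g}]): {exc}"
        ) from exc
    if not np.all(np.isfinite(popt)):
        raise FitError(f"4PL fit produced non-finite parameters {popt}")
    model = FourPL(A=popt[0], D=popt[1], C=abs(popt[2]), B=popt[3] * np.sign(popt[2]))
    fitted = model.predict(x)
    resid = y - fitted
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    stderr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(4, np.nan)
    return FourPLResult(
        model=model,
        r_squared=r2,
        stderr=stderr,
        cov=pcov,
        fitted=fitted,
        residuals=resid,
        n_obs=x.size,
    )


def invert_4pl(model: FourPL, signal: float) -> float:
    """Closed-form dose for a measured signal.

        x = C * ((A - D) / (y - D) - 1)^(1 / B)

    The signal must lie strictly between the asymptotes A and D.
    """
    y = float(signal)
    lo, hi = sorted((model.A, model.D))
    if not lo < y < hi:
        raise ConfigError(
            f"signal {y:g} is outside the open asymptote interval "
            f"({lo:g}, {hi:g}); concentration is undefined there"
        )
    ratio = (model.A - model.D) / (y - model.D) - 1.0
    return float(model.C * ratio ** (1.0 / model.B))
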