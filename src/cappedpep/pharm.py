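"""Dose-response (4PL) and first-order decay fits.

``fit_4pl`` fits the four-parameter logistic used for receptor
dose-response data, response = bottom + (top-bottom)/(1+(ec50/dose)^hill),
parameterized internally on log10(dose) for conditioning. ``fit_decay``
fits A*exp(-k*t) for plasma-stability time courses and reports the
half-life ln(2)/k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["DoseResponseFit", "DecayFit", "fit_4pl", "fit_decay"]


@dataclass(frozen=True)
class DoseResponseFit:
    bottom: float
    top: float
    ec50: float
    hill: float
    rss: float

    @property
    def log10_ec50(self) -> float:
        return math.log10(self.ec50)


@dataclass(frozen=True)
class DecayFit:
    amplitude: float
    rate: float  # 1/min
    rss: float

    @property
    def t_half(self) -> float:
        return math.log(2) / self.rate


def _logistic(logd, bottom, top, log_ec50, hill):
    # extreme starts can overflow the power; the limit (bottom) is correct
    with np.errstate(over="ignore"):
        return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - logd) * hill))


def fit_4pl(doses: np.ndarray, responses: np.ndarray) -> DoseResponseFit:
    """Least-squares 4PL fit with multi-start initialization.

    Requires >= 5 dose levels spanning >= 2 log units. The fit is run
    from a small deterministic grid of (EC50, hill) starts and the lowest
    residual sum of squares wins; the result is canonicalized so
    top >= bottom (flipping the sign of hill when needed).
    """
    d = np.asarray(doses, dtype=float)
    r = np.asarray(responses, dtype=float)
    if np.any(d <= 0):
        raise ValueError("doses must be positive molar concentrations")
    levels = np.unique(d)
    if len(levels) < 5:
        raise ValueError("need at least 5 dose levels")
    span = math.log10(levels.max() / levels.min())
    if span < 2:
        raise ValueError("doses must span at least 2 log units")
    logd = np.log10(d)

    best = None
    lo, hi = float(r.min()), float(r.max())
    starts = [
        (lo, hi, mid, h)
        for mid in np.linspace(logd.min(), logd.max(), 5)
        for h in (0.5, 1.0, 2.0, -1.0)
    ]
    for p0 in starts:
        try:
            popt, _ = curve_fit(_logistic, logd, r, p0=p0, maxfev=20000)
        except RuntimeError:
            continue
        rss = float(np.sum((r - _logistic(logd, *popt)) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise RuntimeError("4PL fit failed to converge from any start")
    (bottom, top, log_ec50, hill), rss = best
    if bottom > top:  # canonical ordering: top >= bottom
        bottom, top, hill = top, bottom, -hill
    return DoseResponseFit(float(bottom), float(top), 10.0 ** float(log_ec50),
                           float(hill), rss)


def fit_decay(times: np.ndarray, levels: np.ndarray) -> DecayFit:
    """Nonlinear least-squares fit of A*exp(-k t) on the raw scale.

    Initialized from a log-linear regression over the positive
    observations, so late near-zero points are honored by the raw-scale
    fit without breaking the initializer.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(levels, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 time points")
    if np.any(y < 0):
        raise ValueError("levels must be non-negative")
    pos = y > 0
    if not pos.any():
        raise ValueError("all levels are zero; nothing to fit")
    if pos.sum() >= 2 and np.ptp(t[pos]) > 0:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        k0 = max(-slope, 1e-6)
        a0 = math.exp(intercept)
    else:
        k0, a0 = 0.01, float(y.max())
    popt, _ = curve_fit(
        lambda tt, a, k: a * np.exp(-k * tt), t, y, p0=(a0, k0), maxfev=20000
    )
    a, k = (float(v) for v in popt)
    rss = float(np.sum((y - a * np.exp(-k * t)) ** 2))
    if k <= 0:
        raise RuntimeError(f"fitted rate is non-positive (k={k:g}); no decay")
    return DecayFit(a, k, rss)
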