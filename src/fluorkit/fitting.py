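"""Curve fitting: one-phase exponential kinetics and 4-parameter logistic.

The exponential association model y(t) = offset + A·(1 − e^(−t/τ)) (rise)
or y(t) = offset + A·e^(−t/τ) (decay) yields the kinetic time constant τ of
sensor activation/deactivation.  The four-parameter logistic (Hill equation)
y = bottom + (top − bottom)/(1 + (EC₅₀/x)^h) yields the half-maximal
effective concentration of a titration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["KineticsFit", "DoseResponseFit", "fit_exp_association", "fit_4pl"]


@dataclass
class KineticsFit:
    """One-phase exponential fit result.

    tau is in seconds; amplitude and offset are in the units of the fitted
    signal; r_squared ∈ [0, 1]; converged is False when the optimiser failed
    (parameters then hold the best initial guess, never silent NaN).
    """

    tau: float
    amplitude: float
    offset: float
    r_squared: float
    converged: bool
    direction: str = "rise"


@dataclass
class DoseResponseFit:
    """Four-parameter logistic fit result (EC₅₀ in the dose units supplied)."""

    ec50: float
    hill_slope: float
    top: float
    bottom: float
    r_squared: float
    converged: bool


def _r_squared(y, y_hat):
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 0.0
    return max(0.0, min(1.0, 1.0 - ss_res / ss_tot))


def fit_exp_association(t, y, direction: str = "rise") -> KineticsFit:
    """Least-squares one-phase exponential fit.

    Parameters
    ----------
    t, y : array_like
        Sample times (s) and values; time is referenced to ``t[0]``.
        Also accepts a trace object with ``times``/``values`` as ``t``
        (then ``y`` must be None).
    direction : {"rise", "decay"}
        rise: y = offset + A(1 − e^(−t/τ)); decay: y = offset + A·e^(−t/τ).

    Initialisation is data-driven: offset from the first decile of the
    values, amplitude from the range, τ from the time to 63% of the range;
    τ is bounded to (0, 10 × duration].
    """
    if y is None:
        t, y = t.times, t.values
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if direction not in ("rise", "decay"):
        raise ValueError("direction must be 'rise' or 'decay'")
    if len(t) < 10:
        raise ValueError("need at least 10 samples to fit kinetics")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite samples")
    tt = t - t[0]
    duration = tt[-1] if tt[-1] > 0 else 1.0

    rng_y = float(np.ptp(y))
    if direction == "rise":
        off0 = float(np.percentile(y, 10))
        amp0 = rng_y
        target = off0 + 0.632 * amp0
        above = np.nonzero(y >= target)[0]
        model = lambda x, tau, amp, off: off + amp * (1.0 - np.exp(-x / tau))
    else:
        off0 = float(np.percentile(y, 10))
        amp0 = float(y[0] - off0)
        target = y[0] - 0.632 * (y[0] - off0)
        above = np.nonzero(y <= target)[0]
        model = lambda x, tau, amp, off: off + amp * np.exp(-x / tau)
    tau0 = float(tt[above[0]]) if len(above) else duration / 3.0
    tau0 = min(max(tau0, duration / 1e3), 10.0 * duration)

    p0 = (tau0, amp0, off0)
    bounds = ([1e-12, -np.inf, -np.inf], [10.0 * duration, np.inf, np.inf])
    try:
        popt, _ = curve_fit(model, tt, y, p0=p0, bounds=bounds, maxfev=20000)
        tau, amp, off = (float(v) for v in popt)
        r2 = _r_squared(y, model(tt, *popt))
        converged = True
    except (RuntimeError, ValueError):
        tau, amp, off = p0
        r2 = 0.0
        converged = False
    return KineticsFit(tau=tau, amplitude=amp, offset=off, r_squared=r2,
                       converged=converged, direction=direction)


def _logistic_log10(logx, log_ec50, hill, top, bottom):
    # bottom + (top-bottom)/(1 + (EC50/x)^hill) with (EC50/x)^h = 10^(h*(logE-logx))
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ec50 - logx)))


def fit_4pl(doses, responses, normalize: bool = False) -> DoseResponseFit:
    """Fit the four-parameter logistic on log₁₀(dose).

    Zero doses are mapped to a pseudo-dose two decades below the smallest
    nonzero dose for fit stability.  With ``normalize=True`` the responses
    are first rescaled to [0, 1] by their min/max (normalised dose–response
    curves); fitted top/bottom are then on that scale.

    The orientation is canonicalised so top ≥ bottom; decreasing data fit
    with a negative Hill slope.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if len(doses) != len(responses):
        raise ValueError("doses and responses must have equal length")
    if len(np.unique(doses)) < 4:
        raise ValueError("need at least 4 distinct doses")
    if np.any(doses < 0):
        raise ValueError("doses must be >= 0")

    if normalize:
        lo, hi = float(np.min(responses)), float(np.max(responses))
        if hi > lo:
            responses = (responses - lo) / (hi - lo)

    nz = doses[doses > 0]
    if len(nz) == 0:
        raise ValueError("all doses are zero")
    pseudo = nz.min() / 100.0
    logx = np.log10(np.where(doses > 0, doses, pseudo))

    if np.ptp(responses) == 0:
        return DoseResponseFit(ec50=float(np.median(nz)), hill_slope=1.0,
                               top=float(responses[0]),
                               bottom=float(responses[0]),
                               r_squared=0.0, converged=False)

    p0 = (float(np.median(logx)), 1.0,
          float(np.max(responses)), float(np.min(responses)))
    bounds = ([logx.min() - 4, -10.0, -np.inf, -np.inf],
              [logx.max() + 4, 10.0, np.inf, np.inf])
    try:
        popt, _ = curve_fit(_logistic_log10, logx, responses, p0=p0,
                            bounds=bounds, maxfev=20000)
        log_ec50, hill, top, bottom = (float(v) for v in popt)
        if top < bottom:  # equivalent re-parameterisation
            top, bottom, hill = bottom, top, -hill
        r2 = _r_squared(responses, _logistic_log10(logx, *popt))
        converged = True
    except (RuntimeError, ValueError):
        log_ec50, hill, top, bottom = p0
        if top < bottom:
            top, bottom = bottom, top
        r2 = 0.0
        converged = False
    return DoseResponseFit(ec50=10.0 ** log_ec50, hill_slope=hill, top=top,
                           bottom=bottom, r_squared=r2, converged=converged)
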