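"""Non-compartmental analysis of sampled concentration profiles.

AUC_last uses the linear trapezoidal rule over the observed points; the
terminal half-life comes from a log-linear regression on the documented
terminal window (points after the last dose end, or the last three points,
whichever window is larger).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class InputError(ValueError):
    pass


class EstimationError(ValueError):
    pass


def _times_conc(profile, window=None):
    t = np.asarray(profile.times, dtype=float)
    c = np.asarray(profile.plasma_concentration, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise InputError("times must be strictly increasing")
    if window is not None:
        lo, hi = window
        mask = (t >= lo) & (t <= hi)
        t, c = t[mask], c[mask]
    return t, c


def auc_last(profile, window=None) -> float:
    """Linear-trapezoid AUC from the first to the last observed sample (mg·h/L)."""
    t, c = _times_conc(profile, window)
    if t.size < 2:
        raise InputError("need at least two points for AUC")
    return float(np.trapezoid(c, t))


def cmax_tmax(profile, window=None) -> tuple[float, float]:
    """Maximum observed concentration and its earliest time."""
    t, c = _times_conc(profile, window)
    if t.size < 1:
        raise InputError("need at least one point")
    i = int(np.argmax(c))  # argmax returns the first (earliest) maximum
    return float(c[i]), float(t[i])


def terminal_half_life(profile, window=None, last_dose_end: float | None = None) -> float:
    """Terminal half-life (h) by log-linear regression.

    The regression window is ``window`` if given; otherwise all points
    after ``last_dose_end``, or the final three points if that leaves
    fewer than three.
    """
    t, c = _times_conc(profile)
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
    elif last_dose_end is not None and np.sum(t > last_dose_end) >= 3:
        mask = t > last_dose_end
    else:
        mask = np.zeros_like(t, dtype=bool)
        mask[-3:] = True
    t, c = t[mask], c[mask]
    if t.size < 3:
        raise EstimationError("need at least three terminal points")
    if np.any(c <= 0):
        raise EstimationError("non-positive terminal concentrations")
    slope, _ = np.polyfit(t, np.log(c), 1)
    if slope >= 0:
        raise EstimationError("terminal slope is non-negative")
    return float(np.log(2.0) / -slope)


def nca_table(profiles: dict, last_dose_end: float | None = None) -> pd.DataFrame:
    """NCA results for a set of profiles keyed by id."""
    rows = []
    for pid, prof in profiles.items():
        cmax, tmax = cmax_tmax(prof)
        row = {"id": pid, "auc_last": auc_last(prof), "cmax": cmax, "tmax": tmax}
        try:
            row["t_half"] = terminal_half_life(prof, last_dose_end=last_dose_end)
        except EstimationError:
            row["t_half"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
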