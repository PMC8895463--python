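"""In vitro dose-response analysis: percent-of-control activity and IC50.

Enzyme activity is measured as the fluorescence gain over the reaction
window (T20 - T0) and expressed as a percentage of the vehicle (DMSO)
control. Inhibition curves over a dilution series are fit with the
four-parameter logistic (4PL) in log concentration,

    activity(c) = bottom + (top - bottom) / (1 + (c / ic50)^hill),

by least squares over every replicate point (not concentration means).
Asymptotes are free by default, constrained to 0 <= bottom <= top (the fit
is parameterized as bottom plus a non-negative span, each bounded by 120 %
so the ordering constraint is a simple box); a fixed-asymptote variant
(top=100, bottom=0) is selectable.

The reported IC50 follows the assay's definition — the concentration at
which activity falls to 50 % of the vehicle control — i.e. the absolute
IC50 solved from the fitted curve,

    ic50 = mid * ((top - 50) / (50 - bottom))^(1/hill),

where ``mid`` is the curve midpoint (inflection). When the fitted
asymptotes do not straddle 50 % the absolute crossing does not exist; the
midpoint is reported instead and the fit is flagged ``extrapolated``. With
fixed asymptotes (100/0) the two definitions coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

# The seven-point, roughly 3-fold dilution series used by the reference assay (uM).
DEFAULT_CONCENTRATIONS_UM = (125.0, 42.0, 14.0, 4.6, 1.5, 0.5, 0.17)

MIN_SIGNAL_SPAN = 10.0  # percentage points of activity needed to call a fit


class AssayError(ValueError):
    pass


@dataclass
class InhibitionCurve:
    """Percent-of-control activity at each concentration, per replicate.

    ``activity`` has shape (n_concentrations, n_replicates); replicate
    counts are equal across concentrations.
    """

    concentrations: np.ndarray
    activity: np.ndarray

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.activity = np.atleast_2d(np.asarray(self.activity, dtype=float))
        if self.activity.shape[0] != len(self.concentrations):
            raise AssayError("one activity row per concentration required")
        if np.any(self.concentrations <= 0):
            raise AssayError("concentrations must be strictly positive")


@dataclass
class Ic50Fit:
    ic50: Optional[float]          # uM, 50 %-of-control crossing
    hill_slope: Optional[float]
    top: Optional[float]           # percent of control
    bottom: Optional[float]
    r_squared: Optional[float]
    converged: bool
    extrapolated: bool = False     # 50 % crossing outside the fitted range
    midpoint: Optional[float] = None  # uM, curve inflection ((top+bottom)/2 level)
    message: str = ""


def percent_of_control(sample_t0, sample_t20, control_t0, control_t20):
    """100 * (sample_t20 - sample_t0) / (control_t20 - control_t0).

    Accepts scalars or arrays; a non-positive control delta is an assay
    failure, not a number.
    """
    control_delta = np.asarray(control_t20, dtype=float) - np.asarray(control_t0, dtype=float)
    if np.any(control_delta <= 0):
        raise AssayError("non-positive control fluorescence delta")
    sample_delta = np.asarray(sample_t20, dtype=float) - np.asarray(sample_t0, dtype=float)
    out = 100.0 * sample_delta / control_delta
    return float(out) if out.ndim == 0 else out


def four_pl(c, log_ic50, hill, bottom, span):
    """4PL in the (bottom, span) parameterization; c in linear units."""
    return bottom + span / (1.0 + np.exp(hill * (np.log(c) - log_ic50)))


def _initial_guess(conc: np.ndarray, mean_act: np.ndarray):
    order = np.argsort(conc)
    conc_s, act_s = conc[order], mean_act[order]
    top0 = float(act_s[0])       # lowest concentration
    bottom0 = float(act_s[-1])   # highest concentration
    mid = (top0 + bottom0) / 2.0
    # interpolated crossing of the midpoint in log concentration
    log_ic50 = math.log(math.sqrt(conc_s[0] * conc_s[-1]))
    for i in range(len(conc_s) - 1):
        a, b = act_s[i], act_s[i + 1]
        if (a - mid) * (b - mid) <= 0 and a != b:
            f = (a - mid) / (a - b)
            log_ic50 = (1 - f) * math.log(conc_s[i]) + f * math.log(conc_s[i + 1])
            break
    return log_ic50, top0, bottom0


def fit_ic50(curve: InhibitionCurve, fix_asymptotes: bool = False) -> Ic50Fit:
    """Least-squares 4PL fit; never returns a silent number on failure.

    Requires >= 4 distinct concentrations. A curve whose activity stays on
    one side of 50 % is fit but flagged ``extrapolated``; a curve with no
    dose response (activity span below ~10 points) is reported as
    non-converged with a diagnostic message.
    """
    conc = curve.concentrations
    if len(np.unique(conc)) < 4:
        raise AssayError("at least 4 distinct concentrations required")

    mean_act = curve.activity.mean(axis=1)
    c_all = np.repeat(conc, curve.activity.shape[1])
    y_all = curve.activity.ravel()

    if float(mean_act.max() - mean_act.min()) < MIN_SIGNAL_SPAN:
        return Ic50Fit(None, None, None, None, None, converged=False,
                       message="no dose response: activity span "
                               f"{mean_act.max() - mean_act.min():.1f} < {MIN_SIGNAL_SPAN}")

    log_ic50_0, top0, bottom0 = _initial_guess(conc, mean_act)
    extrapolated = not (mean_act.min() < 50.0 < mean_act.max())

    lo_c, hi_c = math.log(conc.min()) - 4.0, math.log(conc.max()) + 4.0
    if fix_asymptotes:
        def model(c, log_ic50, hill):
            return four_pl(c, log_ic50, hill, 0.0, 100.0)
        p0 = [np.clip(log_ic50_0, lo_c, hi_c), 1.0]
        bounds = ([lo_c, 0.05], [hi_c, 10.0])
    else:
        model = four_pl
        p0 = [np.clip(log_ic50_0, lo_c, hi_c), 1.0,
              float(np.clip(bottom0, 0, 119)), float(np.clip(top0 - bottom0, 1, 119))]
        bounds = ([lo_c, 0.05, 0.0, 0.0], [hi_c, 10.0, 120.0, 120.0])

    try:
        popt, _ = curve_fit(model, c_all, y_all, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        return Ic50Fit(None, None, None, None, None, converged=False,
                       extrapolated=extrapolated, message=f"fit failed: {exc}")

    if fix_asymptotes:
        log_ic50, hill = popt
        bottom, span = 0.0, 100.0
    else:
        log_ic50, hill, bottom, span = popt
    top = bottom + span
    midpoint = float(np.exp(log_ic50))

    resid = y_all - model(c_all, *popt)
    ss_tot = float(np.sum((y_all - y_all.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else None

    # absolute IC50: solve the fitted curve for activity = 50 % of control
    if bottom < 50.0 < top:
        ic50 = float(midpoint * ((top - 50.0) / (50.0 - bottom)) ** (1.0 / hill))
    else:
        ic50 = midpoint  # crossing outside the fitted asymptotes
        extrapolated = True

    return Ic50Fit(
        ic50=ic50,
        hill_slope=float(hill),
        top=float(top),
        bottom=float(bottom),
        r_squared=r2,
        converged=True,
        extrapolated=extrapolated,
        midpoint=midpoint,
    )


# ---------------------------------------------------------------------------
# I/O

def read_assay_csv(path) -> dict:
    """Fluorescence CSV -> InhibitionCurve per compound.

    Columns: compound, concentration_uM, replicate, t0, t20. Control wells
    use compound == 'control' (their mean delta normalizes each plate).
    """
    df = pd.read_csv(path)
    ctrl = df[df["compound"].str.lower() == "control"]
    if ctrl.empty:
        raise AssayError("no control rows")
    control_delta = float((ctrl["t20"] - ctrl["t0"]).mean())
    if control_delta <= 0:
        raise AssayError("non-positive control fluorescence delta")

    curves = {}
    for compound, grp in df[df["compound"].str.lower() != "control"].groupby("compound"):
        piv = grp.pivot_table(index="concentration_uM", columns="replicate",
                              values=["t0", "t20"])
        conc = piv.index.to_numpy(dtype=float)[::-1]  # descending
        deltas = (piv["t20"] - piv["t0"]).to_numpy(dtype=float)[::-1]
        activity = 100.0 * deltas / control_delta
        curves[compound] = InhibitionCurve(concentrations=conc, activity=activity)
    return curves


def write_fits_csv(fits: dict, path) -> pd.DataFrame:
    rows = []
    for compound, fit in fits.items():
        rows.append(
            dict(compound=compound, ic50_uM=fit.ic50, hill_slope=fit.hill_slope,
                 top=fit.top, bottom=fit.bottom, r_squared=fit.r_squared,
                 converged=fit.converged, extrapolated=fit.extrapolated,
                 message=fit.message)
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
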