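"""Ternary-complex biophysics: hook-effect fits, off-rates, cooperativity.

Steady-state ternary-complex SPR responses against PROTAC concentration are
bell-shaped ("hook effect"): at low concentration ternary complex builds up,
at saturating concentration binary complexes dominate and the signal falls.
The model is the product of an ascending and a descending hyperbola,

    R(c) = rmax * [c / (kd_rise + c)] * [kd_fall / (kd_fall + c)],

whose two apparent K_Ds are the midpoints of the two sigmoidal transitions on
a log-concentration axis and whose peak sits at sqrt(kd_rise * kd_fall).
Dissociation traces restricted to the low-concentration transition are fit
with a single-exponential 1:1 model; the residence time is reported as the
inverse of the off-rate (a ln(2)/koff half-life option is provided).
Cooperativity is summarized as the fold-shift of paired IC50s measured with
and without the saturating partner protein.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import t as t_dist

from .exceptions import FitError, ValidationError
from .synthetic_screen import bell_isotherm


@dataclass
class TernaryFit:
    kd_app_rise: float
    kd_app_fall: float
    rmax: float
    peak_conc: float
    rss: float
    n: int

    def predict(self, conc) -> np.ndarray:
        return bell_isotherm(np.asarray(conc, dtype=float), self.kd_app_rise,
                             self.kd_app_fall, self.rmax)


@dataclass
class DissociationFit:
    koff: float  # 1/s
    residence_time: float  # s
    amplitude: float
    baseline: float
    rss: float
    n: int


@dataclass
class CooperativityShift:
    ic50_binary: float
    ic50_ternary: float
    fold_shift: float  # > 1 means tighter apparent binding with partner


def fit_bell(concentrations, responses) -> TernaryFit:
    """Fit the hook-effect isotherm; monotone data raises (a rise-then-fall
    shape is required — use a binary 1:1 model instead).

    K_Ds are fit in log space for positivity and canonically ordered
    (kd_rise <= kd_fall; the swapped parameterization with rescaled rmax is
    the same curve).
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if c.shape != y.shape or c.ndim != 1:
        raise ValidationError("concentrations and responses must be 1-D, aligned")
    if np.any(c <= 0):
        raise ValidationError("concentrations must be > 0")
    if np.unique(c).size < 6:
        raise FitError("need >= 6 concentrations spanning the peak")
    order = np.argsort(c)
    y_ord = y[order]
    imax = int(np.argmax(y_ord))
    if imax == 0 or imax == y_ord.size - 1:
        raise FitError(
            "response is monotone over the tested range (no hook); "
            "a binary model is more appropriate"
        )

    c_peak = float(c[order][imax])

    def model(cc, log_kd1, log_kd2, log_rmax):
        return bell_isotherm(cc, np.exp(log_kd1), np.exp(log_kd2),
                             np.exp(log_rmax))

    p0 = [np.log(c_peak / 10.0), np.log(c_peak * 10.0),
          np.log(max(float(y.max()), 1e-12) * 2.0)]
    try:
        popt, _ = curve_fit(model, c, y, p0=p0, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"bell fit did not converge: {exc}") from exc
    kd1, kd2, rmax = (float(np.exp(v)) for v in popt)
    if kd1 > kd2:
        # swap transitions; rmax rescales to keep the identical curve
        kd1, kd2, rmax = kd2, kd1, rmax * kd1 / kd2
    resid = y - bell_isotherm(c, kd1, kd2, rmax)
    return TernaryFit(
        kd_app_rise=kd1,
        kd_app_fall=kd2,
        rmax=rmax,
        peak_conc=float(np.sqrt(kd1 * kd2)),
        rss=float(np.sum(resid**2)),
        n=int(c.size),
    )


def fit_dissociation(
    time, response, half_life_convention: bool = False
) -> DissociationFit:
    """Fit R(t) = baseline + amplitude * exp(-koff * t) to a decaying trace.

    ``residence_time`` is 1/koff by default (the off-rate inversion
    convention); with ``half_life_convention`` it is ln(2)/koff.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(response, dtype=float)
    if t.shape != y.shape or t.ndim != 1 or t.size < 4:
        raise ValidationError("need aligned 1-D time/response with >= 4 points")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("time must be strictly increasing")
    span = float(y.max() - y.min())
    head = float(np.mean(y[: max(2, t.size // 10)]))
    tail = float(np.mean(y[-max(2, t.size // 10):]))
    if span <= 0 or (head - tail) < 0.1 * span or head <= tail:
        raise FitError("trace is not decaying; nothing to fit")

    def model(tt, baseline, amplitude, koff):
        return baseline + amplitude * np.exp(-koff * tt)

    k0 = 1.0 / max((t[-1] - t[0]) / 3.0, 1e-12)
    p0 = [tail, head - tail, k0]
    try:
        popt, _ = curve_fit(
            model, t, y, p0=p0,
            bounds=([-np.inf, 0.0, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"dissociation fit did not converge: {exc}") from exc
    baseline, amplitude, koff = (float(v) for v in popt)
    resid = y - model(t, *popt)
    residence = (np.log(2.0) if half_life_convention else 1.0) / koff
    return DissociationFit(
        koff=koff,
        residence_time=float(residence),
        amplitude=amplitude,
        baseline=baseline,
        rss=float(np.sum(resid**2)),
        n=int(t.size),
    )


def cooperativity_shift(
    ic50_binary: float, ic50_ternary: float
) -> CooperativityShift:
    """Fold-shift of apparent affinity with the partner protein present."""
    if ic50_binary <= 0 or ic50_ternary <= 0:
        raise ValidationError("IC50s must be > 0")
    return CooperativityShift(
        ic50_binary=ic50_binary,
        ic50_ternary=ic50_ternary,
        fold_shift=ic50_binary / ic50_ternary,
    )


def initial_velocity(
    time, signal, window_fraction: float = 0.2, curvature_alpha: float = 0.05
) -> float:
    """Initial reaction rate: OLS slope over the earliest fraction of the
    trace, shrinking the window while significant curvature (quadratic term,
    p < ``curvature_alpha``) is detected."""
    t = np.asarray(time, dtype=float)
    y = np.asarray(signal, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValidationError("time and signal must be 1-D and aligned")
    if not 0 < window_fraction <= 1:
        raise ValidationError("window_fraction must be in (0, 1]")
    span = t[-1] - t[0]
    frac = window_fraction
    while True:
        mask = t <= t[0] + frac * span
        if mask.sum() < 5:
            raise FitError(
                f"fewer than 5 points in the initial window (fraction {frac:g})"
            )
        tt, yy = t[mask], y[mask]
        if _curvature_significant(tt, yy, curvature_alpha) and mask.sum() > 5:
            frac /= 2.0
            if (t <= t[0] + frac * span).sum() < 5:
                break  # cannot shrink further; use the smallest valid window
            continue
        break
    mask = t <= t[0] + frac * span
    slope = float(np.polyfit(t[mask], y[mask], 1)[0])
    return slope


def _curvature_significant(t: np.ndarray, y: np.ndarray, alpha: float) -> bool:
    if t.size < 6:
        return False
    try:
        coefs, cov = np.polyfit(t, y, 2, cov=True)
    except (np.linalg.LinAlgError, ValueError):
        return False
    se = float(np.sqrt(cov[0, 0]))
    if not np.isfinite(se) or se == 0:
        return False
    tstat = abs(coefs[0]) / se
    dof = t.size - 3
    p = 2.0 * t_dist.sf(tstat, dof)
    return bool(p < alpha)
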