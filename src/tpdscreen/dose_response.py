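"""Degradation pharmacology: 4PL fits, DC50/Abs-DC50/Dmax, GI50, V/D window.

Degradation curves follow the descending convention: responses are fractions
of the DMSO control signal, so the fitted lower plateau gives the maximal
degradation Dmax = 1 - bottom, the 4PL midpoint is the relative DC50, and the
absolute DC50 is where the fitted curve crosses 50% of control (solved
analytically from the fitted parameters; absent when the curve never spans
0.5). The viability window V/D = GI50 / DC50 uses the top assessed dose in
place of a missing GI50 or DC50.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import FitError, ValidationError
from .synthetic_screen import four_pl


@dataclass
class DoseResponseFit:
    bottom: float
    top: float
    ec50: float
    hill: float
    rel_dc50: float
    abs_dc50: float | None
    dmax: float
    rss: float
    n: int

    def predict(self, dose) -> np.ndarray:
        return four_pl(np.asarray(dose, dtype=float), self.bottom, self.top,
                       self.ec50, self.hill)


@dataclass
class ViabilityWindow:
    gi50: float | None
    dc50: float | None
    top_dose: float
    vd_score: float
    gi50_fallback_used: bool
    dc50_fallback_used: bool


def percent_inhibition(sample: float, high_ctrl: float, low_ctrl: float) -> float:
    """[(high - sample) / (high - low)] x 100; not clipped to [0, 100]."""
    if high_ctrl == low_ctrl:
        raise ValidationError("high and low controls are equal (zero window)")
    return (high_ctrl - sample) / (high_ctrl - low_ctrl) * 100.0


def fit_4pl(doses, responses) -> DoseResponseFit:
    """Least-squares 4PL fit y = bottom + (top-bottom)/(1 + (x/ec50)^hill).

    ``top`` is the zero-dose asymptote after canonicalization (bottom <= top;
    a bottom/top swap with hill sign flip leaves the curve unchanged).
    Initialization comes from the data quartiles. Replicates are fit pointwise
    (plain least squares, no weighting).
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("doses and responses must be 1-D and aligned")
    if np.any(x <= 0):
        raise ValidationError("doses must be > 0")
    if np.unique(x).size < 4:
        raise FitError("need >= 4 distinct dose levels for a 4PL fit")

    lo, hi = float(np.min(y)), float(np.max(y))
    order = np.argsort(x)
    # descending data => hill > 0 in this parameterization
    first, last = np.mean(y[order][:2]), np.mean(y[order][-2:])
    hill0 = 1.0 if first >= last else -1.0
    mid = 0.5 * (lo + hi)
    ec50_0 = float(np.exp(np.interp(mid, np.sort(y), np.log(x[np.argsort(y)]))))
    if not np.isfinite(ec50_0) or ec50_0 <= 0:
        ec50_0 = float(np.sqrt(x.min() * x.max()))
    p0 = [lo, hi, ec50_0, hill0]
    try:
        popt, _ = curve_fit(
            four_pl, x, y, p0=p0,
            bounds=([-np.inf, -np.inf, 1e-12, -50.0],
                    [np.inf, np.inf, np.inf, 50.0]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"4PL fit did not converge: {exc}") from exc
    bottom, top, ec50, hill = (float(v) for v in popt)
    if bottom > top:  # canonical orientation, identical curve
        bottom, top, hill = top, bottom, -hill
    resid = y - four_pl(x, bottom, top, ec50, hill)
    abs_dc50 = _abs_dc50(bottom, top, ec50, hill)
    return DoseResponseFit(
        bottom=bottom,
        top=top,
        ec50=ec50,
        hill=hill,
        rel_dc50=ec50,
        abs_dc50=abs_dc50,
        dmax=float(np.clip(1.0 - bottom, 0.0, 1.0)),
        rss=float(np.sum(resid**2)),
        n=int(x.size),
    )


def _abs_dc50(bottom: float, top: float, ec50: float,
              hill: float) -> float | None:
    """Dose where the fitted curve crosses 0.5 (DMSO-normalized scale);
    absent when 0.5 is outside (bottom, top)."""
    if not (bottom < 0.5 < top) or hill == 0:
        return None
    return float(ec50 * ((top - 0.5) / (0.5 - bottom)) ** (1.0 / hill))


def ratiometric_degradation(
    gfp, mch, bg_gfp: float, bg_mch: float, dmso_ratio: float
) -> float:
    """Fractional degradation from background-subtracted GFP/mCherry.

    Technical replicates are reduced medians-first: median GFP and median
    mCherry, then the ratio of the background-subtracted medians, normalized
    to the DMSO ratio. Returns NaN when mCherry does not rise above its
    background (undefined ratio; flagged, not raised).
    """
    if dmso_ratio <= 0:
        raise ValidationError("dmso_ratio must be > 0")
    gfp_med = float(np.median(np.asarray(gfp, dtype=float)))
    mch_med = float(np.median(np.asarray(mch, dtype=float)))
    if mch_med <= bg_mch:
        return float("nan")
    ratio = (gfp_med - bg_gfp) / (mch_med - bg_mch)
    return 1.0 - ratio / dmso_ratio


def viability_from_gate(
    viable_count: float,
    total_count: float,
    dmso_fraction: float,
    floor: float = 0.25,
) -> tuple[float, bool]:
    """DMSO-relative viability of a treatment and whether it stays above the
    minimal-viability floor (treatments below are excluded from degradation
    fitting)."""
    if total_count <= 0:
        raise ValidationError("total_count must be > 0")
    if viable_count < 0 or viable_count > total_count:
        raise ValidationError("viable_count must be in [0, total_count]")
    if dmso_fraction <= 0:
        raise ValidationError("dmso_fraction must be > 0")
    rel = (viable_count / total_count) / dmso_fraction
    return rel, rel >= floor


def vd_score(
    gi50: float | None, dc50: float | None, top_dose: float
) -> ViabilityWindow:
    """GI50 / DC50 viability-over-degradation window; the top assessed dose
    substitutes for a missing GI50 or DC50. Scores > 1 mean degradation
    precedes toxicity."""
    if top_dose <= 0:
        raise ValidationError("top_dose must be > 0")
    for name, v in (("gi50", gi50), ("dc50", dc50)):
        if v is not None and v <= 0:
            raise ValidationError(f"{name} must be > 0 when present")
    numerator = gi50 if gi50 is not None else top_dose
    denominator = dc50 if dc50 is not None else top_dose
    return ViabilityWindow(
        gi50=gi50,
        dc50=dc50,
        top_dose=top_dose,
        vd_score=numerator / denominator,
        gi50_fallback_used=gi50 is None,
        dc50_fallback_used=dc50 is None,
    )


def dual_reporter_ratio(
    hibit: float, firefly: float, dmso_hibit: float, dmso_firefly: float
) -> float:
    """(HiBiT/Firefly) normalized to the non-treated DMSO control ratio."""
    if min(hibit, firefly, dmso_hibit, dmso_firefly) <= 0:
        raise ValidationError("all reporter signals must be > 0")
    return (hibit / firefly) / (dmso_hibit / dmso_firefly)


def fit_flow_table(
    table,
    bg_gfp: float,
    bg_mch: float,
    viability_floor: float = 0.25,
) -> tuple[DoseResponseFit, DoseResponseFit | None, ViabilityWindow]:
    """Full flow-cytometry workflow on a (dose, median_gfp, median_mch,
    viable_fraction) table with a DMSO row convention: the ratio at the lowest
    dose tail is taken as the DMSO reference when no explicit reference is
    given — callers with a true DMSO well should normalize beforehand.

    Doses whose DMSO-relative viability falls below the floor are excluded
    from the degradation fit (but kept for the viability fit). Returns the
    degradation fit, the viability fit (None if it fails), and the V/D window.
    """
    dose = np.asarray(table["dose"], dtype=float)
    gfp = np.asarray(table["median_gfp"], dtype=float)
    mch = np.asarray(table["median_mch"], dtype=float)
    viable = np.asarray(table["viable_fraction"], dtype=float)
    ratio = (gfp - bg_gfp) / (mch - bg_mch)
    dmso_ratio = float(ratio[np.argmin(dose)])
    dmso_viable = float(viable[np.argmin(dose)])
    rel_viab = viable / dmso_viable
    keep = rel_viab >= viability_floor
    if keep.sum() < 4:
        raise FitError("fewer than 4 doses above the viability floor")
    deg_fit = fit_4pl(dose[keep], ratio[keep] / dmso_ratio)
    try:
        viab_fit = fit_4pl(dose, rel_viab)
        gi50 = viab_fit.ec50 if viab_fit.bottom < 0.5 else None
    except FitError:
        viab_fit, gi50 = None, None
    dc50 = deg_fit.rel_dc50 if deg_fit.dmax > 0.1 else None
    window = vd_score(gi50, dc50, top_dose=float(dose.max()))
    return deg_fit, viab_fit, window


def gi50_from_fit(fit: DoseResponseFit) -> float | None:
    """GI50 as the midpoint of a descending DMSO-relative viability fit,
    absent when the curve never reaches half-killing."""
    if fit.bottom < 0.5 < fit.top:
        return fit.ec50
    return None
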