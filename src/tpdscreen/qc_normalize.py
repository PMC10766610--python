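"""Firefly QC gate, plate-wise nonlinear normalization, and robust z-scores.

The Firefly signal tracks per-well cell number; wells whose Firefly does not
exceed 1.25x the plate's media/non-infected control reference (i.e.
log10(firefly/reference) > log10(1.25)) are excluded from everything
downstream. On each assay plate the HiBiT ~ Firefly relation is fit with a
third-order polynomial over QC-passing library wells (optionally with one
robust re-fit pass so rare rescuer wells do not bend the baseline), and each
well's activity is the ratio of observed to predicted HiBiT (``rel_change``).
Rescue activity is then expressed as a robust z-score of ``rel_change``,
computed per assay plate by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, FitError, ValidationError
from .screen_io import PlateWell

MIN_LOG10_RATIO = math.log10(1.25)
MAD_SCALE = 1.4826  # consistency factor: scaled MAD estimates sigma for normal data

_QC_REFERENCE_CLASSES = ("media_ctrl", "uninfected_ctrl")


@dataclass
class NormalizedWell:
    """A plate well after QC gating and Firefly normalization."""

    plate_id: str
    replicate_id: str
    well_id: str
    gene_id: str
    well_class: str
    hibit_rlu: float
    firefly_rlu: float
    firefly_log10_ratio: float = float("nan")
    qc_pass: bool = False
    qc_reason: str = ""
    predicted_hibit: float = float("nan")
    rel_change: float = float("nan")
    robust_z: float = float("nan")
    domain_clamped: bool = False

    @property
    def plate_key(self) -> tuple[str, str]:
        return (self.plate_id, self.replicate_id)

    @property
    def well_key(self) -> tuple[str, str, str]:
        return (self.plate_id, self.replicate_id, self.well_id)


@dataclass
class PlatePolynomial:
    """Degree-3 polynomial of HiBiT as a function of Firefly, one per assay
    plate, in the power basis (c0 + c1*x + c2*x^2 + c3*x^3)."""

    plate_id: str
    replicate_id: str
    coefficients: tuple[float, float, float, float]
    fit_domain: tuple[float, float]
    n_points_used: int

    def predict(self, firefly: float) -> tuple[float, bool]:
        """Predicted HiBiT; Firefly outside the fit domain is clamped to the
        domain edge (returned flag marks clamping)."""
        lo, hi = self.fit_domain
        clamped = firefly < lo or firefly > hi
        x = min(max(firefly, lo), hi)
        c0, c1, c2, c3 = self.coefficients
        return c0 + c1 * x + c2 * x**2 + c3 * x**3, clamped


def firefly_qc(
    wells: list[PlateWell], min_log10_ratio: float = MIN_LOG10_RATIO
) -> list[NormalizedWell]:
    """Gate wells on the Firefly cell-number control.

    Per assay plate, the reference is the median Firefly of that plate's
    media/non-infected control wells; a well passes when
    log10(firefly / reference) exceeds ``min_log10_ratio``.
    """
    by_plate: dict[tuple[str, str], list[PlateWell]] = {}
    for w in wells:
        by_plate.setdefault(w.plate_key, []).append(w)

    out: list[NormalizedWell] = []
    for key, plate_wells in by_plate.items():
        refs = [
            w.firefly_rlu for w in plate_wells
            if w.well_class in _QC_REFERENCE_CLASSES
        ]
        if not refs:
            raise ConfigError(
                f"plate {key} has no media/uninfected control wells for the "
                "Firefly QC reference"
            )
        reference = float(np.median(refs))
        for w in plate_wells:
            if w.firefly_rlu > 0 and reference > 0:
                ratio = math.log10(w.firefly_rlu / reference)
            else:
                ratio = float("-inf")
            passed = ratio > min_log10_ratio
            out.append(
                NormalizedWell(
                    plate_id=w.plate_id,
                    replicate_id=w.replicate_id,
                    well_id=w.well_id,
                    gene_id=w.gene_id,
                    well_class=w.well_class,
                    hibit_rlu=w.hibit_rlu,
                    firefly_rlu=w.firefly_rlu,
                    firefly_log10_ratio=ratio,
                    qc_pass=passed,
                    qc_reason="" if passed else "firefly_below_threshold",
                )
            )
    return out


def fit_plate_polynomial(
    wells: list[NormalizedWell], robustify: bool = True
) -> PlatePolynomial:
    """Fit HiBiT ~ poly3(Firefly) over one plate's QC-passing library wells.

    With ``robustify``, points with absolute residual above 3 scaled-MADs of
    the residuals are dropped and the polynomial re-fit once; this keeps rare
    strong rescuers from bending the plate baseline.
    """
    pts = [w for w in wells if w.well_class == "library" and w.qc_pass]
    if not pts:
        raise FitError("no QC-passing library wells to fit")
    keys = {w.plate_key for w in pts}
    if len(keys) != 1:
        raise ValidationError(f"wells from multiple plates passed: {sorted(keys)}")
    plate_id, replicate_id = keys.pop()
    x = np.array([w.firefly_rlu for w in pts], dtype=float)
    y = np.array([w.hibit_rlu for w in pts], dtype=float)
    if x.size < 5:
        raise FitError(
            f"plate {(plate_id, replicate_id)}: {x.size} points < 5 required"
        )
    if np.ptp(x) == 0:
        raise FitError(
            f"plate {(plate_id, replicate_id)}: all Firefly values equal "
            "(singular design)"
        )

    def _fit(xx: np.ndarray, yy: np.ndarray) -> np.polynomial.Polynomial:
        # fit in a mapped domain for conditioning, convert to power basis
        return np.polynomial.Polynomial.fit(xx, yy, deg=3)

    poly = _fit(x, y)
    n_used = x.size
    if robustify:
        resid = y - poly(x)
        mad = MAD_SCALE * np.median(np.abs(resid - np.median(resid)))
        if mad > 0:
            keep = np.abs(resid) <= 3.0 * mad
            if keep.sum() >= 5 and keep.sum() < x.size:
                poly = _fit(x[keep], y[keep])
                n_used = int(keep.sum())
    coefs = poly.convert().coef
    coefs = np.pad(coefs, (0, 4 - coefs.size))[:4]
    return PlatePolynomial(
        plate_id=plate_id,
        replicate_id=replicate_id,
        coefficients=tuple(float(c) for c in coefs),
        fit_domain=(float(x.min()), float(x.max())),
        n_points_used=n_used,
    )


def normalize_wells(
    wells: list[NormalizedWell],
    polynomials: dict[tuple[str, str], PlatePolynomial],
) -> list[NormalizedWell]:
    """Fill ``predicted_hibit`` and ``rel_change`` in place (and return the
    list). A non-positive prediction flags the well as QC-failed with a
    reason rather than raising."""
    for w in wells:
        if not w.qc_pass or w.well_class in _QC_REFERENCE_CLASSES:
            continue
        if w.plate_key not in polynomials:
            raise ConfigError(f"no plate polynomial for {w.plate_key}")
        pred, clamped = polynomials[w.plate_key].predict(w.firefly_rlu)
        w.domain_clamped = clamped
        if pred <= 0:
            w.qc_pass = False
            w.qc_reason = "nonpositive_predicted_hibit"
            continue
        w.predicted_hibit = pred
        w.rel_change = w.hibit_rlu / pred
    return wells


def robust_zscore(values) -> np.ndarray:
    """(x - median) / (1.4826 * MAD); falls back to SD when MAD = 0, and to
    all-zeros when the SD is 0 too."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or np.sum(np.isfinite(x)) < 5:
        raise ValidationError("robust_zscore needs >= 5 finite values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad > 0:
        return (x - med) / (MAD_SCALE * mad)
    sd = np.std(x)
    if sd > 0:
        return (x - med) / sd
    return np.zeros_like(x)


def apply_robust_z(
    wells: list[NormalizedWell], scope: str = "per_plate"
) -> list[NormalizedWell]:
    """Robust z of ``rel_change`` over QC-passing library wells, computed per
    assay plate (default) or screen-wide."""
    if scope not in ("per_plate", "global"):
        raise ConfigError("z scope must be 'per_plate' or 'global'")
    lib = [
        w for w in wells
        if w.well_class == "library" and w.qc_pass and np.isfinite(w.rel_change)
    ]
    groups: dict[tuple, list[NormalizedWell]] = {}
    for w in lib:
        key = w.plate_key if scope == "per_plate" else ("global",)
        groups.setdefault(key, []).append(w)
    for group in groups.values():
        z = robust_zscore([w.rel_change for w in group])
        for w, zi in zip(group, z):
            w.robust_z = float(zi)
    return wells


def normalize_screen(
    wells: list[PlateWell],
    min_log10_ratio: float = MIN_LOG10_RATIO,
    robustify: bool = True,
    z_scope: str = "per_plate",
) -> tuple[list[NormalizedWell], dict[tuple[str, str], PlatePolynomial]]:
    """QC gate -> per-plate polynomial fit -> rel_change -> robust z."""
    normed = firefly_qc(wells, min_log10_ratio)
    by_plate: dict[tuple[str, str], list[NormalizedWell]] = {}
    for w in normed:
        by_plate.setdefault(w.plate_key, []).append(w)
    polys = {
        key: fit_plate_polynomial(group, robustify=robustify)
        for key, group in by_plate.items()
    }
    normalize_wells(normed, polys)
    apply_robust_z(normed, scope=z_scope)
    return normed, polys
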